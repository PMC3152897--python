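"""Protein-interaction network data model, file I/O, and component extraction.

Networks are carried as :class:`networkx.Graph` objects whose nodes are
opaque, case-sensitive protein/gene identifiers.  Loaded graphs are always
*simple*: self-loops (homodimers in PPI databases) are dropped and counted,
duplicate edges are collapsed, and ``{A, B}`` equals ``{B, A}``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkParseError",
    "EmptyNetworkError",
    "NetworkSummary",
    "read_network",
    "write_network",
    "largest_component",
    "connected_components",
    "summarize",
]


class NetworkParseError(ValueError):
    """A line of a network file could not be parsed; carries the line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class EmptyNetworkError(ValueError):
    """Raised when an operation requires a non-empty network."""


@dataclass(frozen=True)
class NetworkSummary:
    """Global topological description of a protein-interaction network.

    ``mean_degree`` is the standard ``2 * n_edges / n_nodes`` (0 for an
    empty graph); ``giant_size`` is the node count of the largest connected
    component.
    """

    n_nodes: int
    n_edges: int
    mean_degree: float
    n_components: int
    giant_size: int


def _clean_edges(raw_edges: Iterable[tuple[str, str]]) -> tuple[nx.Graph, int, int]:
    """Build a simple graph; return (graph, n_self_loops, n_duplicates)."""
    g = nx.Graph()
    self_loops = 0
    duplicates = 0
    for u, v in raw_edges:
        if u == v:
            self_loops += 1
            g.add_node(u)
            continue
        if g.has_edge(u, v):
            duplicates += 1
            continue
        g.add_edge(u, v)
    return g, self_loops, duplicates


def read_network(
    path,
    format: str = "edge-list",
    header: bool = False,
) -> nx.Graph:
    """Read an undirected protein network from an edge list or SIF file.

    Parameters
    ----------
    path : path-like
        Tab- or whitespace-delimited text file.  Lines starting with ``#``
        are comments.  Edge-list lines need >= 2 fields (extra columns are
        ignored); SIF lines are ``A relation B [C ...]`` and expand to
        pairwise edges from ``A`` to each listed target.
    format : {"edge-list", "sif"}
    header : bool
        Skip the first non-comment line (column headers are never
        auto-detected).

    Returns
    -------
    networkx.Graph
        A simple graph.  ``G.graph["load_report"]`` records the counts of
        dropped self-loops and collapsed duplicate edges.

    Raises
    ------
    NetworkParseError
        On a malformed data line (with its line number).
    EmptyNetworkError
        If the file contains no edges and no nodes.
    """
    if format not in ("edge-list", "sif"):
        raise ValueError(f"unknown network format: {format!r}")
    path = Path(path)
    raw: list[tuple[str, str]] = []
    skipped_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if header and not skipped_header:
                skipped_header = True
                continue
            fields = line.split()
            if format == "edge-list":
                if len(fields) < 2:
                    raise NetworkParseError(
                        path, lineno, f"expected >=2 fields, got {len(fields)}"
                    )
                raw.append((fields[0], fields[1]))
            else:  # sif
                if len(fields) < 3:
                    raise NetworkParseError(
                        path, lineno, f"SIF line needs >=3 fields, got {len(fields)}"
                    )
                source = fields[0]
                for target in fields[2:]:
                    raw.append((source, target))
    if not raw:
        raise EmptyNetworkError(f"{path}: no edges found")
    g, self_loops, duplicates = _clean_edges(raw)
    g.graph["load_report"] = {
        "source": str(path),
        "format": format,
        "n_self_loops_dropped": self_loops,
        "n_duplicate_edges_collapsed": duplicates,
    }
    if self_loops or duplicates:
        logger.info(
            "%s: dropped %d self-loop(s), collapsed %d duplicate edge(s)",
            path, self_loops, duplicates,
        )
    return g


def write_network(net: nx.Graph, path) -> None:
    """Write the canonical two-column tab-delimited edge list.

    Each edge is written with its endpoints in lexicographic order, and
    edges are sorted lexicographically, so equal networks serialize to
    byte-identical files.
    """
    pairs = sorted(tuple(sorted(e)) for e in net.edges())
    with open(path, "w") as fh:
        for u, v in pairs:
            fh.write(f"{u}\t{v}\n")


def connected_components(net: nx.Graph) -> list[set]:
    """Connected components sorted by (size descending, smallest member)."""
    comps = [set(c) for c in nx.connected_components(net)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def largest_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties on size are broken by the lexicographically smallest member node,
    so the result is deterministic.
    """
    if net.number_of_nodes() == 0:
        raise EmptyNetworkError("cannot take the largest component of an empty network")
    giant = connected_components(net)[0]
    return net.subgraph(giant).copy()


def summarize(net: nx.Graph) -> NetworkSummary:
    """Node/edge counts, mean degree, and component structure."""
    n = net.number_of_nodes()
    m = net.number_of_edges()
    comps = [len(c) for c in nx.connected_components(net)] if n else []
    return NetworkSummary(
        n_nodes=n,
        n_edges=m,
        mean_degree=(2.0 * m / n) if n else 0.0,
        n_components=len(comps),
        giant_size=max(comps) if comps else 0,
    )
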