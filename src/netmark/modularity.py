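"""Greedy modularity-maximization clustering and per-module topology stats.

A *module* is a group of proteins whose internal edge count exceeds the
expectation under degree-preserving random rewiring.  The objective is the
Newman-Girvan modularity

    Q = sum_c [ e_c / m  -  (d_c / 2m)^2 ]

where, for each module c, ``e_c`` is the number of intra-module edges,
``d_c`` the degree sum of its members, and ``m`` the total edge count.  The
second term is the configuration-model expectation of the first.

Clustering is agglomerative (Clauset-Newman-Moore style): start from
singletons, repeatedly merge the *connected* pair of modules with the
largest positive modularity gain, stop when no merge improves Q.  Ties on
the gain are broken by the lexicographically smallest module-id pair so the
result is reproducible without a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .net_core import EmptyNetworkError
from .topology import traffic_all

logger = logging.getLogger(__name__)

__all__ = ["ModulePartition", "modularity_q", "greedy_modules", "module_stats"]

MODULE_STATS_COLUMNS = ["module_id", "NP", "IntraMI", "InterMI", "TotInt", "MTraffic"]

_TIE_EPS = 1e-12


@dataclass
class ModulePartition:
    """Disjoint modules covering all nodes of the clustered graph.

    Attributes
    ----------
    assignment : dict node -> int
        Total map from node to 1-based module id; ids are ordered by module
        size (descending), ties by smallest member node.
    q : float
        Modularity of the assignment.
    merge_log : list of ((id_a, id_b), delta_q)
        The accepted merges in order.  During merging a module is
        identified by its lexicographically smallest member node.
    small_modules : list of int
        Ids of modules smaller than the requested minimum size (reported,
        not removed).
    """

    assignment: dict = field(repr=False)
    q: float
    merge_log: list = field(default_factory=list, repr=False)
    small_modules: list = field(default_factory=list)

    def modules(self) -> dict[int, set]:
        """Module id -> member node set."""
        out: dict[int, set] = {}
        for node, mid in self.assignment.items():
            out.setdefault(mid, set()).add(node)
        return out

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))


def modularity_q(net: nx.Graph, assignment: dict) -> float:
    """Modularity Q of an explicit node -> module assignment."""
    m = net.number_of_edges()
    if m == 0:
        raise EmptyNetworkError("modularity is undefined for an edgeless network")
    missing = set(net.nodes()) - set(assignment)
    if missing:
        raise ValueError(f"assignment missing {len(missing)} node(s), e.g. {sorted(missing)[:3]}")
    intra: dict = {}
    degsum: dict = {}
    for node in net.nodes():
        degsum[assignment[node]] = degsum.get(assignment[node], 0) + net.degree(node)
    for u, v in net.edges():
        if assignment[u] == assignment[v]:
            intra[assignment[u]] = intra.get(assignment[u], 0) + 1
    q = 0.0
    for c, d_c in degsum.items():
        q += intra.get(c, 0) / m - (d_c / (2.0 * m)) ** 2
    return q


def greedy_modules(net: nx.Graph, min_size: int = 3) -> ModulePartition:
    """Agglomerative modularity maximization from singleton modules.

    Works on connected and disconnected simple graphs with at least one
    edge.  Modules smaller than ``min_size`` are flagged in
    ``small_modules`` but kept (the partition stays total).
    """
    m = net.number_of_edges()
    if m == 0:
        raise EmptyNetworkError("cannot cluster an edgeless network")
    # Module state keyed by representative node (lexicographic min member).
    members: dict[str, set] = {n: {n} for n in net.nodes()}
    degsum: dict[str, int] = {n: net.degree(n) for n in net.nodes()}
    intra: dict[str, int] = {n: 0 for n in net.nodes()}
    # neighbor weights: nbr[i][j] = number of edges between modules i and j
    nbr: dict[str, dict[str, int]] = {n: {} for n in net.nodes()}
    for u, v in net.edges():
        nbr[u][v] = nbr[u].get(v, 0) + 1
        nbr[v][u] = nbr[v].get(u, 0) + 1

    merge_log: list = []
    two_m_sq = (2.0 * m) ** 2
    while True:
        best_dq = 0.0
        best_pair: tuple[str, str] | None = None
        for i, nb in nbr.items():
            for j, e_ij in nb.items():
                if j <= i:
                    continue
                dq = e_ij / m - 2.0 * degsum[i] * degsum[j] / two_m_sq
                if dq > best_dq + _TIE_EPS or (
                    best_pair is not None
                    and abs(dq - best_dq) <= _TIE_EPS
                    and (i, j) < best_pair
                ):
                    best_dq = dq
                    best_pair = (i, j)
        if best_pair is None or best_dq <= _TIE_EPS:
            break
        i, j = best_pair
        merge_log.append(((i, j), best_dq))
        # Merge j into i (i < j lexicographically, so i stays the min member).
        members[i] |= members.pop(j)
        intra[i] += intra.pop(j) + nbr[i].pop(j)
        degsum[i] += degsum.pop(j)
        for k, w in nbr.pop(j).items():
            if k == i:
                continue
            nbr[k].pop(j)
            nbr[i][k] = nbr[i].get(k, 0) + w
            nbr[k][i] = nbr[i][k]
        nbr[i].pop(j, None)

    # Relabel: 1-based ids, largest module first, ties by smallest member.
    ordered = sorted(members.values(), key=lambda s: (-len(s), min(s)))
    assignment = {node: mid for mid, mod in enumerate(ordered, start=1) for node in mod}
    q = modularity_q(net, assignment)
    small = [mid for mid, mod in enumerate(ordered, start=1) if len(mod) < min_size]
    if small:
        logger.info("%d module(s) smaller than min_size=%d", len(small), min_size)
    return ModulePartition(assignment=assignment, q=q, merge_log=merge_log, small_modules=small)


def module_stats(
    net: nx.Graph,
    partition: ModulePartition,
    traffic: dict | None = None,
) -> pd.DataFrame:
    """Per-module topology table.

    Columns: ``NP`` (member proteins), ``IntraMI`` (edges with both ends
    inside), ``InterMI`` (edges with exactly one end inside), ``TotInt`` =
    IntraMI + InterMI, and ``MTraffic`` — the sum of betweenness centrality
    of the module's nodes computed *on the module's induced subgraph*
    (module-internal traffic, independent of the rest of the network).

    ``traffic`` may carry a precomputed whole-network traffic map; it is
    validated against ``net`` (unknown nodes are an error) but MTraffic is
    always the induced-subgraph quantity.
    """
    if traffic is not None:
        unknown = set(traffic) - set(net.nodes())
        if unknown:
            raise ValueError(
                f"traffic map contains {len(unknown)} node(s) absent from the "
                f"network, e.g. {sorted(unknown)[:3]}"
            )
    assignment = partition.assignment
    missing = set(net.nodes()) - set(assignment)
    if missing:
        raise ValueError(f"partition does not cover {len(missing)} node(s)")
    modules = partition.modules()
    intra = {mid: 0 for mid in modules}
    inter = {mid: 0 for mid in modules}
    for u, v in net.edges():
        cu, cv = assignment[u], assignment[v]
        if cu == cv:
            intra[cu] += 1
        else:
            inter[cu] += 1
            inter[cv] += 1
    rows = []
    for mid in sorted(modules):
        nodes = modules[mid]
        sub = net.subgraph(nodes)
        mtraffic = float(sum(traffic_all(sub).values()))
        rows.append(
            {
                "module_id": mid,
                "NP": len(nodes),
                "IntraMI": intra[mid],
                "InterMI": inter[mid],
                "TotInt": intra[mid] + inter[mid],
                "MTraffic": mtraffic,
            }
        )
    return pd.DataFrame(rows, columns=MODULE_STATS_COLUMNS)
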