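"""Seeded generators for networks, annotations, expression matrices, and
qPCR Ct tables with the statistical structure the pipeline assumes.

Every generator is a pure function of its scenario (seed included) built
on ``numpy.random.default_rng`` (PCG64), so outputs are identical across
runs and platforms for a given numpy generation.

The planted-partition network emulates a sparse protein-interaction
network with dense modules; the expression generator emulates a two-class
post-MI cohort (default 16 good / 16 poor, matching the study design the
pipeline targets) with Gaussian noise on a log-intensity-like scale and
class effects injected into chosen genes, plus ejection-fraction values
consistent with the 40% outcome rule (good: uniform on 45-73%, poor:
uniform on 20-40%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import AnnotationCollection
from .expression import GOOD, POOR, CtTable, ExpressionDataset

__all__ = [
    "NetworkScenario",
    "ExpressionScenario",
    "synth_network",
    "synth_expression",
    "synth_annotations",
    "synth_ct",
    "paper_shaped_preset",
]


def _gene_ids(n: int, prefix: str = "G") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class NetworkScenario:
    """Planted-partition graph parameters.

    Within-block edges appear with probability ``p_in``, between-block
    edges with ``p_out``; ``p_in > p_out`` plants recoverable modules.
    """

    block_sizes: tuple
    p_in: float
    p_out: float
    seed: int

    def __post_init__(self):
        object.__setattr__(self, "block_sizes", tuple(int(b) for b in self.block_sizes))
        if any(b < 3 for b in self.block_sizes):
            raise ValueError("block sizes must be >= 3")
        if not (0 < self.p_in <= 1):
            raise ValueError("p_in must be in (0, 1]")
        if not (0 <= self.p_out < 1):
            raise ValueError("p_out must be in [0, 1)")
        if self.p_in <= self.p_out:
            raise ValueError("planted modules require p_in > p_out")


def synth_network(sc: NetworkScenario) -> tuple[nx.Graph, dict[str, int]]:
    """Sample a planted-partition graph; returns (graph, node -> block id).

    Blocks are 1-based.  All nodes are added to the graph even if
    isolated, so the planted assignment is total.
    """
    rng = np.random.default_rng(sc.seed)
    n = sum(sc.block_sizes)
    names = _gene_ids(n)
    blocks: dict[str, int] = {}
    offsets = []
    pos = 0
    for bid, size in enumerate(sc.block_sizes, start=1):
        offsets.append(pos)
        for i in range(pos, pos + size):
            blocks[names[i]] = bid
        pos += size
    g = nx.Graph()
    g.add_nodes_from(names)
    nb = len(sc.block_sizes)
    for bi in range(nb):
        for bj in range(bi, nb):
            p = sc.p_in if bi == bj else sc.p_out
            if p == 0:
                continue
            ni, nj = sc.block_sizes[bi], sc.block_sizes[bj]
            mask = rng.random((ni, nj)) < p
            if bi == bj:
                mask = np.triu(mask, k=1)
            rows, cols = np.nonzero(mask)
            oi, oj = offsets[bi], offsets[bj]
            g.add_edges_from(
                (names[oi + r], names[oj + c]) for r, c in zip(rows, cols)
            )
    return g, blocks


@dataclass(frozen=True)
class ExpressionScenario:
    """Two-class expression-matrix parameters.

    ``de_genes`` maps gene id -> effect size in units of the within-class
    noise SD; the effect is added to the poor-outcome class.
    """

    n_genes: int
    n_good: int = 16
    n_poor: int = 16
    de_genes: tuple = field(default_factory=tuple)  # ((gene, effect), ...)
    noise_sd: float = 1.0
    baseline: float = 8.0
    seed: int = 0
    gene_ids: tuple | None = None

    def __post_init__(self):
        if isinstance(self.de_genes, dict):
            object.__setattr__(self, "de_genes", tuple(sorted(self.de_genes.items())))
        else:
            object.__setattr__(self, "de_genes", tuple(self.de_genes))
        if self.gene_ids is not None:
            object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
            if len(self.gene_ids) != self.n_genes:
                raise ValueError("gene_ids length must equal n_genes")
        if self.n_good < 2 or self.n_poor < 2:
            raise ValueError("need at least 2 samples per class")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        ids = self.gene_ids if self.gene_ids is not None else _gene_ids(self.n_genes)
        unknown = {g for g, _ in self.de_genes} - set(ids)
        if unknown:
            raise ValueError(f"de_genes not among generated genes: {sorted(unknown)[:5]}")


def synth_expression(sc: ExpressionScenario) -> ExpressionDataset:
    """Sample a genes x samples matrix with planted class effects."""
    rng = np.random.default_rng(sc.seed)
    genes = list(sc.gene_ids) if sc.gene_ids is not None else _gene_ids(sc.n_genes)
    n_samples = sc.n_good + sc.n_poor
    samples = [f"S{i:02d}" for i in range(1, n_samples + 1)]
    labels = pd.Series([GOOD] * sc.n_good + [POOR] * sc.n_poor, index=samples)
    values = sc.baseline + rng.normal(0.0, sc.noise_sd, size=(sc.n_genes, n_samples))
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    poor_cols = labels.index[labels == POOR]
    for gene, effect in sc.de_genes:
        matrix.loc[gene, poor_cols] += effect * sc.noise_sd
    ef = pd.Series(
        np.concatenate([
            rng.uniform(45.0, 73.0, sc.n_good),
            rng.uniform(20.0, 40.0, sc.n_poor),
        ]),
        index=samples,
    )
    return ExpressionDataset(matrix=matrix, labels=labels, ef=ef)


def synth_annotations(
    universe,
    n_null_terms: int,
    planted=None,
    seed: int = 0,
    namespace: str = "BP",
) -> AnnotationCollection:
    """Gene-set collection with random null terms and planted terms.

    Null term sizes are drawn uniformly from 5-50 (capped at the universe
    size); planted terms — ``(term_id, gene set)`` pairs — are included
    verbatim and must lie inside the universe.
    """
    universe = sorted(set(universe))
    rng = np.random.default_rng(seed)
    terms: dict[str, set] = {}
    for tid, genes in (planted or []):
        genes = set(genes)
        if not genes <= set(universe):
            raise ValueError(f"planted term {tid!r} has genes outside the universe")
        terms[tid] = genes
    for i in range(1, n_null_terms + 1):
        size = int(rng.integers(5, 51))
        size = min(size, len(universe))
        terms[f"NULL{i:04d}"] = set(rng.choice(universe, size=size, replace=False))
    return AnnotationCollection(namespace=namespace, terms=terms, universe=set(universe))


def synth_ct(
    n_samples: int,
    genes,
    reference: str,
    seed: int = 0,
) -> CtTable:
    """Sample a plausible qPCR Ct table (samples x genes).

    Cycle thresholds land in roughly 15-35 cycles; the housekeeping
    reference gene has low between-sample variance (stable expression),
    the other genes vary more.  Per-sample loading shifts are shared
    across genes, which delta-Ct normalization cancels.
    """
    genes = list(genes)
    if reference not in genes:
        raise ValueError(f"reference {reference!r} not among genes")
    rng = np.random.default_rng(seed)
    samples = [f"P{i:02d}" for i in range(1, n_samples + 1)]
    gene_mean = {g: float(rng.uniform(18.0, 30.0)) for g in genes}
    loading = rng.normal(0.0, 0.5, n_samples)  # per-sample RNA input shift
    data = {}
    for g in genes:
        sd = 0.05 if g == reference else 0.8
        data[g] = gene_mean[g] + loading + rng.normal(0.0, sd, n_samples)
    ct = pd.DataFrame(data, index=samples).clip(lower=15.0, upper=35.0)
    return CtTable(ct=ct, reference_gene=reference)


def paper_shaped_preset(seed: int, scale: float = 1.0) -> dict:
    """The end-to-end demo scenario: a study-sized synthetic cohort.

    A ~2500-node sparse network (mean degree ~5) of 100 planted 25-node
    blocks, one of which is the prognostic module: its genes carry a
    0.8-SD class effect, with a 5-gene signature core at 1.5 SD; three
    high-degree nodes elsewhere act as differentially expressed
    bottlenecks (1.5 SD).  The expression cohort is 16 good / 16 poor.
    Annotations include one term planted on a network block and one on
    the signature core; an 11-sample Ct table covers the bottleneck genes
    plus a stable reference.  ``scale`` < 1 shrinks the network (block
    count) for quick runs; the cohort design is unchanged.

    Returns a dict with keys ``network``, ``blocks``, ``expression``,
    ``annotations``, ``ct``, ``prognostic_genes``, ``bottleneck_genes``,
    ``scenario``.
    """
    n_blocks = max(4, int(round(100 * scale)))
    sizes = [25] * n_blocks
    sc = NetworkScenario(
        block_sizes=tuple(sizes),
        p_in=0.15,
        p_out=min(0.05, 0.0006 / scale if scale else 0.0006),
        seed=seed,
    )
    net, blocks = synth_network(sc)
    genes = sorted(net.nodes())
    # The last block is the planted prognostic module.  Its five
    # lexicographically first genes form the strong signature core (the
    # small-module biomarker the pipeline should surface); the remaining
    # members carry a weaker effect.  Greedy modularity maximization cannot
    # resolve communities far below sqrt(2m) total degree, so the planted
    # module is block-sized rather than 5 genes.
    prognostic_block = n_blocks
    block_genes = sorted(g for g, b in blocks.items() if b == prognostic_block)
    prognostic_genes = block_genes[:5]
    # The three highest-degree nodes outside the prognostic block stand in
    # for differentially expressed bottlenecks (degree tracks traffic).
    bottleneck_genes = sorted(
        (g for g in genes if blocks[g] != prognostic_block),
        key=lambda g: (-net.degree(g), g),
    )[:3]
    effects = {g: 0.8 for g in block_genes}
    effects.update({g: 1.5 for g in prognostic_genes})
    effects.update({g: 1.5 for g in bottleneck_genes})
    expr_sc = ExpressionScenario(
        n_genes=len(genes),
        n_good=16,
        n_poor=16,
        de_genes=effects,
        noise_sd=1.0,
        baseline=8.0,
        seed=seed + 1,
        gene_ids=tuple(genes),
    )
    ds = synth_expression(expr_sc)
    first_block_genes = {g for g, b in blocks.items() if b == 1}
    annotations = synth_annotations(
        universe=genes,
        n_null_terms=40,
        planted=[
            ("PLANTED_BLOCK1", set(first_block_genes)),
            ("PLANTED_PROGNOSTIC", set(prognostic_genes)),
        ],
        seed=seed + 2,
        namespace="BP",
    )
    ct = synth_ct(
        n_samples=11,
        genes=bottleneck_genes + ["REF"],
        reference="REF",
        seed=seed + 3,
    )
    return {
        "network": net,
        "blocks": blocks,
        "expression": ds,
        "annotations": annotations,
        "ct": ct,
        "prognostic_genes": prognostic_genes,
        "bottleneck_genes": bottleneck_genes,
        "scenario": sc,
    }
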