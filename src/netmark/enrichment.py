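"""Annotation-set association testing for network modules.

Each (module, term) pair is tested with a two-tailed Fisher exact test on
the 2x2 table of membership counts over a gene universe, and p-values are
Benjamini-Hochberg adjusted across all pairs within one annotation
namespace (GO BP, GO CC, or miRNA target sets).  Associations with
adjusted p below alpha (default 0.01) are flagged significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationCollection",
    "read_gmt",
    "write_gmt",
    "fisher_two_tailed",
    "bh_adjust",
    "enrich_modules",
]

ENRICHMENT_COLUMNS = [
    "module_id", "namespace", "term_id",
    "a", "b", "c", "d", "p_raw", "p_adj", "significant",
]


@dataclass
class AnnotationCollection:
    """A namespace of gene sets (GO BP/CC terms, miRNA target sets, ...).

    ``universe`` is the background gene set; every term is a subset of it.
    """

    namespace: str = "other"
    terms: dict[str, set] = field(default_factory=dict)
    universe: set = field(default_factory=set)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for tid, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {tid!r} has an empty gene set")
            extra = genes - self.universe
            if extra:
                raise ValueError(
                    f"term {tid!r} contains genes outside the universe, "
                    f"e.g. {sorted(extra)[:3]}"
                )


def read_gmt(path, namespace: str = "other", universe: set | None = None) -> AnnotationCollection:
    """Load gene sets from a GMT file (term, description, genes...).

    The universe defaults to the union of all term genes; pass an explicit
    ``universe`` to widen the background.
    """
    path = Path(path)
    terms: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            tid, desc, genes = fields[0], fields[1], fields[2:]
            if tid in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term id {tid!r}")
            gene_set = {g for g in genes if g}
            if not gene_set:
                raise ValueError(f"{path}:{lineno}: term {tid!r} has no genes")
            terms[tid] = gene_set
            descriptions[tid] = desc
    union = set().union(*terms.values()) if terms else set()
    if universe is None:
        universe = union
    return AnnotationCollection(
        namespace=namespace, terms=terms, universe=set(universe) | union,
        descriptions=descriptions,
    )


def write_gmt(collection: AnnotationCollection, path) -> None:
    """Write gene sets in GMT format with sorted genes and terms."""
    with open(path, "w") as fh:
        for tid in sorted(collection.terms):
            desc = collection.descriptions.get(tid, "")
            genes = "\t".join(sorted(collection.terms[tid]))
            fh.write(f"{tid}\t{desc}\t{genes}\n")


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Uses the minimum-likelihood rule: the p-value sums the hypergeometric
    probabilities of every table with the same margins whose probability
    does not exceed that of the observed table.  A degenerate margin
    (an empty row or column) gives p = 1.
    """
    for name, x in (("a", a), ("b", b), ("c", c), ("d", d)):
        if x < 0:
            raise ValueError(f"count {name} is negative: {x}")
    if a + b + c + d < 1:
        raise ValueError("table total must be >= 1")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_modules(
    modules,
    annotations: AnnotationCollection,
    alpha: float = 0.01,
    universe: set | None = None,
) -> pd.DataFrame:
    """Fisher-test every (module, term) pair and BH-correct within the namespace.

    Parameters
    ----------
    modules : ModulePartition or mapping module_id -> gene set
    annotations : AnnotationCollection
    alpha : float
        Significance threshold on the adjusted p (default 0.01).
    universe : set, optional
        Background gene set.  Defaults to the clustered genes intersected
        with the annotation universe.

    Returns
    -------
    DataFrame with one row per (module, term) pair: contingency counts
    a, b, c, d, raw and adjusted p, and a significance flag.  Modules whose
    genes do not intersect the universe are dropped (nothing is testable).
    """
    if hasattr(modules, "modules"):
        modules = modules.modules()
    if universe is None:
        member_genes = set().union(*modules.values()) if modules else set()
        universe = member_genes & annotations.universe
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe: no overlap between modules and annotations")
    n_universe = len(universe)
    rows = []
    for mid in sorted(modules):
        mod = set(modules[mid]) & universe
        if not mod:
            continue
        for tid in sorted(annotations.terms):
            term = annotations.terms[tid] & universe
            a = len(mod & term)
            b = len(mod) - a
            c = len(term) - a
            d = n_universe - a - b - c
            rows.append(
                {
                    "module_id": mid,
                    "namespace": annotations.namespace,
                    "term_id": tid,
                    "a": a, "b": b, "c": c, "d": d,
                    "p_raw": fisher_two_tailed(a, b, c, d),
                }
            )
    df = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS if c not in ("p_adj", "significant")])
    if len(df):
        df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
        df["significant"] = df["p_adj"] < alpha
    else:
        df["p_adj"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df[ENRICHMENT_COLUMNS]
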