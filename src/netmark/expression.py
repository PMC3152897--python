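"""Expression matrices, two-class differential expression, and qPCR
delta-Ct normalization.

The outcome labels follow the post-MI ejection-fraction (EF) convention:
*good* outcome is EF > 40% (preserved left-ventricular function), *poor*
outcome is EF <= 40%.  Differential expression between the classes uses
the two-sided Mann-Whitney U test, at the single-gene level and at the
module level (on per-sample module-mean profiles, BH-corrected across
modules).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "GOOD", "POOR", "EF_THRESHOLD",
    "ExpressionDataset", "CtTable",
    "read_expression", "write_expression",
    "mann_whitney", "gene_de_scan",
    "module_mean_profile", "module_de",
    "read_ct", "pcr_normalize",
]

GOOD = "good"
POOR = "poor"
EF_THRESHOLD = 40.0  # percent; EF > 40 => good outcome

DE_COLUMNS = ["unit", "U", "p_nominal", "p_adj", "direction"]


def label_from_ef(ef: float) -> str:
    return GOOD if ef > EF_THRESHOLD else POOR


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with binary outcome labels.

    ``matrix`` has gene identifiers as the index and sample identifiers as
    columns; ``labels`` maps every sample to ``"good"`` or ``"poor"``;
    ``ef`` optionally carries ejection fractions (percent) and must be
    consistent with the labels under the 40% rule.
    """

    matrix: pd.DataFrame
    labels: pd.Series
    ef: pd.Series | None = None

    def __post_init__(self):
        self.matrix = self.matrix.astype(float)
        if self.matrix.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if self.matrix.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        if self.matrix.isna().any().any():
            raise ValueError("missing values in the expression matrix are not allowed")
        self.labels = pd.Series(self.labels).reindex(self.matrix.columns)
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])
            raise ValueError(f"samples without labels: {missing[:5]}")
        bad = set(self.labels.unique()) - {GOOD, POOR}
        if bad:
            raise ValueError(f"labels must be '{GOOD}' or '{POOR}', got {sorted(bad)}")
        if self.ef is not None:
            self.ef = pd.Series(self.ef).reindex(self.matrix.columns)
            derived = self.ef.dropna().map(label_from_ef)
            conflict = derived[derived != self.labels[derived.index]]
            if len(conflict):
                raise ValueError(
                    f"EF/label inconsistency under the {EF_THRESHOLD:.0f}% rule "
                    f"for samples {list(conflict.index)[:5]}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    def class_samples(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


def read_expression(matrix_path, phenotype_path) -> ExpressionDataset:
    """Load a tab-delimited genes x samples matrix plus a phenotype table.

    The phenotype file needs a ``sample`` column and a ``label`` and/or
    ``ef`` column; labels are derived from EF by the 40% rule when absent.
    Every matrix sample must appear in the phenotype table.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    try:
        matrix = matrix.astype(float)
    except ValueError as exc:
        raise ValueError(f"{matrix_path}: non-numeric expression values: {exc}") from exc
    pheno = pd.read_csv(phenotype_path, sep="\t")
    pheno.columns = [c.lower() for c in pheno.columns]
    if "sample" not in pheno.columns:
        raise ValueError(f"{phenotype_path}: missing 'sample' column")
    pheno = pheno.set_index("sample")
    missing = set(matrix.columns) - set(pheno.index)
    if missing:
        raise ValueError(f"samples absent from phenotype file: {sorted(missing)[:5]}")
    pheno = pheno.loc[list(matrix.columns)]
    ef = pheno["ef"].astype(float) if "ef" in pheno.columns else None
    if "label" in pheno.columns:
        labels = pheno["label"].astype(str)
    elif ef is not None:
        labels = ef.map(label_from_ef)
    else:
        raise ValueError(f"{phenotype_path}: need a 'label' or 'ef' column")
    return ExpressionDataset(matrix=matrix, labels=labels, ef=ef)


def write_expression(ds: ExpressionDataset, matrix_path, phenotype_path) -> None:
    ds.matrix.to_csv(matrix_path, sep="\t", index_label="gene")
    pheno = pd.DataFrame({"sample": ds.samples, "label": ds.labels.values})
    if ds.ef is not None:
        pheno["ef"] = ds.ef.values
    pheno.to_csv(phenotype_path, sep="\t", index=False)


def _exact_applicable(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(pooled) <= 20 and len(np.unique(pooled)) == len(pooled)


def mann_whitney(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of x against y.

    Returns ``(U, p)`` where U is the rank-sum statistic of x.  ``mode``:
    ``"exact"`` enumerates the permutation distribution (valid without
    ties), ``"approx"`` uses the normal approximation with tie and
    continuity corrections, ``"auto"`` picks exact when n1 + n2 <= 20 and
    the pooled values are tie-free, otherwise approx.  Data constant
    across both groups gives (n1*n2/2, 1.0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return len(x) * len(y) / 2.0, 1.0
    if mode == "auto":
        mode = "exact" if _exact_applicable(x, y) else "approx"
    method = {"exact": "exact", "approx": "asymptotic"}.get(mode)
    if method is None:
        raise ValueError(f"unknown mode: {mode!r}")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _direction(ds: ExpressionDataset, values: pd.Series) -> int:
    good = values[ds.class_samples(GOOD)]
    poor = values[ds.class_samples(POOR)]
    return int(np.sign(np.median(poor) - np.median(good)))


def gene_de_scan(
    ds: ExpressionDataset,
    genes=None,
    mode: str = "auto",
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-gene Mann-Whitney differential expression between outcome classes.

    ``direction`` is the sign of (median poor - median good).  ``p_adj`` is
    the BH adjustment across the scanned genes (optional).
    """
    if genes is None:
        genes = ds.genes
    else:
        genes = list(genes)
        unknown = sorted(set(genes) - set(ds.genes))
        if unknown:
            raise ValueError(f"genes absent from the dataset: {unknown[:10]}")
    good_s = ds.class_samples(GOOD)
    poor_s = ds.class_samples(POOR)
    rows = []
    for g in genes:
        row = ds.matrix.loc[g]
        u, p = mann_whitney(row[good_s], row[poor_s], mode=mode)
        rows.append({"unit": g, "U": u, "p_nominal": p,
                     "direction": _direction(ds, row)})
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p_nominal"].to_numpy()) if adjust else np.nan
    return df[DE_COLUMNS]


def module_mean_profile(ds: ExpressionDataset, module_genes) -> pd.Series:
    """Per-sample unweighted mean expression over a module's genes.

    Module genes without expression data are dropped with a logged count;
    zero overlap is an error.
    """
    module_genes = set(module_genes)
    present = [g for g in ds.genes if g in module_genes]
    if not present:
        raise ValueError("no module gene has expression data")
    dropped = len(module_genes) - len(present)
    if dropped:
        logger.info("module-mean profile: %d of %d module genes lack expression data",
                    dropped, len(module_genes))
    return ds.matrix.loc[present].mean(axis=0)


def module_de(ds: ExpressionDataset, partition, mode: str = "auto") -> pd.DataFrame:
    """Module-level differential expression on module-mean profiles.

    Each module overlapping the expression data is summarized per sample by
    the mean of its genes, the class difference is tested by Mann-Whitney,
    and p-values are BH-adjusted across the tested modules.
    """
    modules = partition.modules() if hasattr(partition, "modules") else dict(partition)
    good_s = ds.class_samples(GOOD)
    poor_s = ds.class_samples(POOR)
    gene_set = set(ds.genes)
    rows = []
    for mid in sorted(modules):
        if not (set(modules[mid]) & gene_set):
            continue
        profile = module_mean_profile(ds, modules[mid])
        u, p = mann_whitney(profile[good_s], profile[poor_s], mode=mode)
        rows.append({"unit": mid, "U": u, "p_nominal": p,
                     "direction": _direction(ds, profile)})
    if not rows:
        raise ValueError("no module overlaps the expression data")
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p_nominal"].to_numpy())
    return df[DE_COLUMNS]


@dataclass
class CtTable:
    """qPCR cycle-threshold values (samples x genes) with a reference gene."""

    ct: pd.DataFrame
    reference_gene: str

    def __post_init__(self):
        self.ct = self.ct.astype(float)
        if self.reference_gene not in self.ct.columns:
            raise ValueError(f"reference gene {self.reference_gene!r} not measured")
        if self.ct[self.reference_gene].isna().any():
            missing = list(self.ct.index[self.ct[self.reference_gene].isna()])
            raise ValueError(f"reference Ct missing for samples {missing[:5]}")
        if (self.ct <= 0).any().any():
            raise ValueError("Ct values must be positive")


def read_ct(path, reference_gene: str) -> CtTable:
    """Load a tab-delimited samples x genes Ct table."""
    return CtTable(ct=pd.read_csv(path, sep="\t", index_col=0), reference_gene=reference_gene)


def pcr_normalize(table: CtTable) -> pd.DataFrame:
    """Relative expression by delta-Ct against the housekeeping gene.

    expression(sample, gene) = 2 ** (Ct(sample, reference) - Ct(sample, gene));
    the reference gene's own column is identically 1.  Adding a constant to
    every Ct of one sample leaves that sample's values unchanged.
    """
    ref = table.ct[table.reference_gene]
    return 2.0 ** table.ct.rsub(ref, axis=0)
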