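"""End-to-end discovery pipeline: network -> topology -> modules ->
enrichment -> differential expression -> candidate panels -> LOOCV report.

Stages after module detection are optional (a network-only run is valid).
All tables are written tab-delimited into the output directory together
with one deterministic ``summary.json`` (config hash + seed + version, no
timestamps), so a run is reproducible byte-for-byte from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .net_core import largest_component, read_network, summarize
from .topology import degree_traffic_spearman, rank_bottlenecks, topology_table
from .modularity import greedy_modules, module_stats
from .enrichment import enrich_modules, read_gmt
from .expression import gene_de_scan, module_de, pcr_normalize, read_ct, read_expression
from .prognosis import ClassifierConfig, FeaturePanel, loocv_evaluate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "assemble_panels", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs and parameters of a full pipeline run.

    Defaults: top 10 bottlenecks, enrichment alpha 0.01, minimum module
    size 3, ridge 1e-8 — the operating point of the discovery analysis
    this pipeline implements.  Panel-assembly thresholds: genes enter
    panels at nominal p <= ``gene_p`` (default 0.02), modules at corrected
    p <= ``module_p`` (default 0.05).
    """

    network: str
    out_dir: str
    network_format: str = "edge-list"
    expression: str | None = None
    phenotype: str | None = None
    annotations: str | None = None  # GMT path
    ct_table: str | None = None
    ct_reference: str | None = None
    top_k: int = 10
    alpha: float = 0.01
    min_module_size: int = 3
    ridge_lambda: float = 1e-8
    scaler_scope: str = "fold"
    gene_p: float = 0.02
    module_p: float = 0.05
    n_perm: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        for name in ("network", "expression", "phenotype", "annotations", "ct_table"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} path does not exist: {path}")
        if (self.expression is None) != (self.phenotype is None):
            raise ValueError("expression and phenotype must be given together")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.top_k < 1 or self.min_module_size < 1:
            raise ValueError("top_k and min_module_size must be >= 1")

    def content_hash(self) -> str:
        """Hash of the analytical configuration (inputs and parameters).

        The output directory is excluded so re-running the same analysis
        into a different location yields an identical summary.
        """
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All tables produced by one pipeline run, plus provenance."""

    summary: dict
    topology: pd.DataFrame
    bottlenecks: pd.DataFrame
    module_assignment: pd.DataFrame
    module_table: pd.DataFrame
    enrichment: pd.DataFrame | None = None
    gene_de: pd.DataFrame | None = None
    module_de_table: pd.DataFrame | None = None
    panel_evaluations: list = field(default_factory=list)
    pcr: pd.DataFrame | None = None


def assemble_panels(
    topology: pd.DataFrame,
    module_de_table: pd.DataFrame | None,
    gene_de: pd.DataFrame | None,
    module_genes: dict,
    expression_genes,
    top_k: int = 10,
    gene_p: float = 0.02,
    module_p: float = 0.05,
) -> list[FeaturePanel]:
    """Build the three candidate-panel families from a run's tables.

    1. ``module-means``: mean profiles of the modules with corrected
       p <= ``module_p``.
    2. ``module-genes``: the individual genes of those modules that have
       expression data.
    3. ``bottleneck+module``: union of top-``top_k``-traffic genes with
       nominal DE p <= ``gene_p`` and the significant modules' DE genes.

    Returns an empty list (with a warning in the log) when nothing
    qualifies.
    """
    panels: list[FeaturePanel] = []
    expression_genes = set(expression_genes)
    sig_modules: list = []
    if module_de_table is not None and len(module_de_table):
        sig = module_de_table[module_de_table["p_adj"] <= module_p]
        sig_modules = list(sig["unit"])
    if sig_modules:
        panels.append(FeaturePanel(
            name="module-means",
            features=tuple(("module-mean", mid) for mid in sig_modules),
        ))
        indiv = []
        for mid in sig_modules:
            indiv.extend(sorted(set(module_genes[mid]) & expression_genes))
        if indiv:
            panels.append(FeaturePanel(
                name="module-genes",
                features=tuple(("gene", g) for g in dict.fromkeys(indiv)),
            ))
    if gene_de is not None and len(gene_de):
        top = set(rank_bottlenecks(topology, top_k)["protein"])
        de_map = dict(zip(gene_de["unit"], gene_de["p_nominal"]))
        hits = [g for g in sorted(top & set(de_map)) if de_map[g] <= gene_p]
        module_hits = []
        for mid in sig_modules:
            for g in sorted(set(module_genes[mid]) & set(de_map)):
                if de_map[g] <= gene_p:
                    module_hits.append(g)
        combined = list(dict.fromkeys(hits + module_hits))
        if combined:
            panels.append(FeaturePanel(
                name="bottleneck+module",
                features=tuple(("gene", g) for g in combined),
            ))
    if not panels:
        logger.warning("no qualifying genes or modules; no panels assembled")
    return panels


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute every configured stage and write the report.

    Outputs in ``cfg.out_dir``: ``network_summary.tsv``, ``topology.tsv``,
    ``bottlenecks.tsv``, ``modules.tsv`` (membership), ``module_stats.tsv``,
    ``enrichment.tsv``, ``gene_de.tsv``, ``module_de.tsv``,
    ``panel_scores.tsv``, ``pcr_expression.tsv``, and ``summary.json``.
    A stage failure aborts with the failing stage named and leaves a
    ``FAILED`` marker file next to the partial outputs.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "version": __version__,
    }
    stage = "load-network"
    try:
        net = read_network(cfg.network, format=cfg.network_format)
        giant = largest_component(net)
        s = summarize(net)
        gs = summarize(giant)
        summary["network"] = {
            "n_nodes": s.n_nodes, "n_edges": s.n_edges,
            "mean_degree": round(s.mean_degree, 6),
            "n_components": s.n_components,
            "giant_nodes": gs.n_nodes, "giant_edges": gs.n_edges,
        }
        pd.DataFrame([summary["network"]]).to_csv(
            out / "network_summary.tsv", sep="\t", index=False)
        logger.info("network: %d nodes, %d edges; giant %d/%d",
                    s.n_nodes, s.n_edges, gs.n_nodes, gs.n_edges)

        stage = "topology"
        topo = topology_table(giant)
        _write(topo, out / "topology.tsv")
        bn = rank_bottlenecks(topo, cfg.top_k)
        _write(bn, out / "bottlenecks.tsv")
        rho, rho_p = degree_traffic_spearman(topo, n_perm=cfg.n_perm, seed=cfg.seed)
        summary["topology"] = {
            "spearman_rho": round(rho, 6), "spearman_p": rho_p,
            "top_bottlenecks": list(bn["protein"]),
        }

        stage = "modules"
        partition = greedy_modules(giant, min_size=cfg.min_module_size)
        module_genes = {mid: sorted(g) for mid, g in partition.modules().items()}
        assign_df = pd.DataFrame(
            sorted(partition.assignment.items()), columns=["protein", "module_id"])
        _write(assign_df, out / "modules.tsv")
        mstats = module_stats(giant, partition)
        _write(mstats, out / "module_stats.tsv")
        summary["modules"] = {
            "Q": round(partition.q, 6),
            "n_modules": partition.n_modules,
            "small_modules": partition.small_modules,
        }

        report = RunReport(
            summary=summary, topology=topo, bottlenecks=bn,
            module_assignment=assign_df, module_table=mstats,
        )

        if cfg.annotations is not None:
            stage = "enrichment"
            coll = read_gmt(cfg.annotations)
            enr = enrich_modules(partition, coll, alpha=cfg.alpha)
            _write(enr, out / "enrichment.tsv")
            report.enrichment = enr
            summary["enrichment"] = {
                "n_tests": int(len(enr)),
                "n_significant": int(enr["significant"].sum()) if len(enr) else 0,
            }

        if cfg.expression is not None:
            stage = "differential-expression"
            ds = read_expression(cfg.expression, cfg.phenotype)
            gde = gene_de_scan(ds)
            _write(gde, out / "gene_de.tsv")
            mde = module_de(ds, partition)
            _write(mde, out / "module_de.tsv")
            report.gene_de = gde
            report.module_de_table = mde
            summary["differential_expression"] = {
                "n_genes_tested": int(len(gde)),
                "min_gene_p": float(gde["p_nominal"].min()),
                "min_module_p_adj": float(mde["p_adj"].min()),
            }

            stage = "panels"
            panels = assemble_panels(
                topo, mde, gde, module_genes, ds.genes,
                top_k=cfg.top_k, gene_p=cfg.gene_p, module_p=cfg.module_p,
            )
            ccfg = ClassifierConfig(
                ridge_lambda=cfg.ridge_lambda, scaler_scope=cfg.scaler_scope)
            stage = "classification"
            rows = []
            panel_summaries = []
            for panel in panels:
                ev = loocv_evaluate(ds, panel, ccfg, module_genes=module_genes)
                report.panel_evaluations.append(ev)
                panel_summaries.append({
                    "panel": panel.name,
                    "n_features": len(panel.features),
                    "n": len(ev.oof_scores),
                    "auc": round(ev.auc, 6),
                })
                for sample, score in ev.oof_scores.items():
                    rows.append({"panel": panel.name, "sample": sample,
                                 "oof_score": round(float(score), 6),
                                 "label": ds.labels[sample]})
            if rows:
                _write(pd.DataFrame(rows), out / "panel_scores.tsv")
            summary["panels"] = panel_summaries

        if cfg.ct_table is not None:
            stage = "pcr-normalization"
            if cfg.ct_reference is None:
                raise ValueError("ct_reference is required with ct_table")
            ct = read_ct(cfg.ct_table, cfg.ct_reference)
            norm = pcr_normalize(ct)
            norm.to_csv(out / "pcr_expression.tsv", sep="\t", index_label="sample")
            report.pcr = norm
            summary["pcr"] = {"n_samples": int(len(norm)),
                              "reference": cfg.ct_reference}

    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    report.summary = summary
    return report
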