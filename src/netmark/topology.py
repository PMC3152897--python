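"""Node degree and traffic (betweenness centrality), bottleneck ranking, and
the degree-traffic correlation.

*Traffic* of a node v is the betweenness centrality in the unnormalized,
unordered-pair convention: the sum over node pairs (s, t), s != v != t, of
the fraction of shortest s-t paths that pass through v.  High-traffic nodes
are network *bottlenecks*; in disease interactomes they are candidate
biomarkers and drug targets, and ranking by traffic is the first discovery
step of the pipeline.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "degree_all",
    "traffic_all",
    "topology_table",
    "rank_bottlenecks",
    "degree_traffic_spearman",
]

TABLE_COLUMNS = ["protein", "degree", "traffic", "traffic_rank"]


def degree_all(net: nx.Graph) -> dict[str, int]:
    """Degree of every node (number of incident edges)."""
    return dict(net.degree())


def traffic_all(net: nx.Graph) -> dict[str, float]:
    """Betweenness centrality of every node (Brandes accumulation).

    Unnormalized; endpoints excluded; each unordered pair (s, t) contributes
    sigma_st(v)/sigma_st to every intermediate node v.  Nodes of degree <= 1
    get 0.  Disconnected inputs are fine: unreachable pairs contribute
    nothing.
    """
    return nx.betweenness_centrality(net, normalized=False)


def topology_table(net: nx.Graph) -> pd.DataFrame:
    """Per-node degree/traffic table with a deterministic traffic rank.

    Rank 1 is the highest-traffic node; ties are broken by degree
    (descending) then identifier (ascending), so ranks are a permutation of
    1..n.
    """
    deg = degree_all(net)
    tra = traffic_all(net)
    df = pd.DataFrame(
        {
            "protein": list(deg.keys()),
            "degree": [deg[p] for p in deg],
            "traffic": [tra[p] for p in deg],
        }
    )
    df = df.sort_values(
        by=["traffic", "degree", "protein"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df["traffic_rank"] = np.arange(1, len(df) + 1)
    return df


def rank_bottlenecks(table: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k high-traffic nodes from a :func:`topology_table` result."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(table):
        warnings.warn(
            f"k={k} exceeds the {len(table)} available nodes; returning all",
            stacklevel=2,
        )
        k = len(table)
    out = table.sort_values("traffic_rank").head(k).reset_index(drop=True)
    return out


def degree_traffic_spearman(
    table: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    method: str = "permutation",
) -> tuple[float, float]:
    """Spearman correlation between node degree and traffic.

    rho uses average ranks for ties.  With ``method="permutation"`` the
    two-sided p-value comes from a label-permutation null with the add-one
    estimator ``p = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_perm)`` so it
    is never exactly 0; ``method="asymptotic"`` uses the t approximation.
    """
    x = np.asarray(table["degree"], dtype=float)
    y = np.asarray(table["traffic"], dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 nodes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "asymptotic":
        p = float(stats.spearmanr(x, y).pvalue)
        return rho, p
    if method != "permutation":
        raise ValueError(f"unknown method: {method!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    # Pearson on centred ranks; only the permuted dot product changes.
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    hits = 0
    for _ in range(n_perm):
        rho_perm = rxc @ rng.permutation(ryc) / denom
        if abs(rho_perm) >= abs(rho) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return rho, float(p)
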