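"""Three-criterion region-specific gene (RSG) detection and clustering.

A retained gene is region-specific in region ``r`` when, writing ``e`` for its
mean FPKM in ``r`` and ``O`` for its mean FPKM in the other regions:

1. fold dominance — ``e >= fold * aggregate(O)`` (default aggregate: max over
   the other regions, fold 3);
2. fraction-of-others floor — ``e > frac * mean(O)`` (default frac 0.5);
3. expression rank — ``e`` is within the top quantile of retained-gene
   expression in region ``r`` (default top 25%, i.e. at or above the 0.75
   linear-interpolation quantile).

With the max aggregate and fold > 1 a gene can be specific to at most one
region. Detected genes are clustered on row-z-scored region means
(agglomerative, Euclidean distance, complete linkage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = ["RSGParams", "detect_rsg", "rsg_calls_to_list", "cluster_rsg", "RSGClustering"]


@dataclass
class RSGParams:
    fold: float = 3.0
    frac_of_others: float = 0.5
    top_quantile: float = 0.75
    others_aggregate: str = "max"

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("fold must exceed 1")
        if not 0 < self.top_quantile < 1:
            raise ValueError("top_quantile must lie in (0, 1)")
        if self.others_aggregate not in ("max", "mean"):
            raise ValueError(f"unknown others_aggregate {self.others_aggregate!r}")


def detect_rsg(
    region_expr: pd.DataFrame,
    retained: list[str],
    params: RSGParams | None = None,
) -> pd.DataFrame:
    """Evaluate the three specificity criteria on every (gene, region) pair.

    Parameters
    ----------
    region_expr : DataFrame
        Genes x regions mean FPKM.
    retained : list of str
        The analysis universe; only these genes are evaluated, and the
        per-region expression-rank cutoff is computed among them.
    params : RSGParams

    Returns
    -------
    DataFrame with one row per (gene, region) candidate and columns
    mean_fpkm, passes_fold, passes_frac, passes_top, is_rsg; gene rows keep
    input order, regions keep column order.
    """
    params = params or RSGParams()
    if region_expr.shape[1] < 2:
        raise ValueError("region-specific detection needs at least 2 regions")
    if not retained:
        raise ValueError("retained gene list is empty")
    missing = set(retained) - set(region_expr.index)
    if missing:
        raise ValueError(f"retained gene {sorted(missing)[0]!r} not in region means")

    expr = region_expr.loc[retained]
    regions = list(expr.columns)
    E = expr.to_numpy(dtype=float)
    n_r = len(regions)

    # per-region expression-rank cutoff among retained genes
    cutoffs = np.quantile(E, params.top_quantile, axis=0, method="linear")

    rows = []
    for k, r in enumerate(regions):
        e = E[:, k]
        others = np.delete(E, k, axis=1)
        agg = others.max(axis=1) if params.others_aggregate == "max" else others.mean(axis=1)
        passes_fold = e >= params.fold * agg
        passes_frac = e > params.frac_of_others * others.mean(axis=1)
        passes_top = e >= cutoffs[k]
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": expr.index,
                    "region": r,
                    "mean_fpkm": e,
                    "passes_fold": passes_fold,
                    "passes_frac": passes_frac,
                    "passes_top": passes_top,
                }
            )
        )
    calls = pd.concat(rows, ignore_index=True)
    calls["is_rsg"] = calls["passes_fold"] & calls["passes_frac"] & calls["passes_top"]
    # report in gene input order, then region order
    calls["_g"] = calls["gene_id"].map({g: i for i, g in enumerate(expr.index)})
    calls["_r"] = calls["region"].map({r: i for i, r in enumerate(regions)})
    calls = calls.sort_values(["_g", "_r"]).drop(columns=["_g", "_r"]).reset_index(drop=True)
    return calls


def rsg_calls_to_list(calls: pd.DataFrame) -> pd.DataFrame:
    """The positive calls only: one row per detected (gene, region)."""
    return calls.loc[calls["is_rsg"], ["gene_id", "region", "mean_fpkm"]].reset_index(
        drop=True
    )


@dataclass
class RSGClustering:
    zscores: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[str]

    def to_json_dict(self) -> dict:
        return {
            "leaf_order": self.leaf_order,
            "merges": [
                {"left": int(a), "right": int(b), "height": float(h), "size": int(n)}
                for a, b, h, n in self.linkage
            ],
        }


def cluster_rsg(region_expr_rsg: pd.DataFrame) -> RSGClustering:
    """Hierarchically cluster detected genes on row-z-scored region means.

    Each row is standardised across regions (population sd; all-constant rows
    map to all zeros); rows are merged agglomeratively with Euclidean distance
    and complete linkage. Ties break deterministically by input order via
    scipy's stable implementation.
    """
    if region_expr_rsg.shape[0] < 2:
        raise ValueError(
            "need at least 2 detected genes to cluster; skip clustering otherwise"
        )
    X = region_expr_rsg.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = np.where(sd > 0, (X - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    z = pd.DataFrame(Z, index=region_expr_rsg.index, columns=region_expr_rsg.columns)
    link = hierarchy.linkage(Z, method="complete", metric="euclidean")
    leaves = hierarchy.leaves_list(link)
    return RSGClustering(
        zscores=z,
        linkage=link,
        leaf_order=[region_expr_rsg.index[i] for i in leaves],
    )
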