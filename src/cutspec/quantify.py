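"""FPKM quantification, expressed-gene accounting and the retained-gene filter.

FPKM for gene ``g`` in sample ``j`` is

    FPKM_{gj} = c_{gj} * 1e9 / (T_j * L_g)

where ``c`` is the read count, ``T_j`` the sample's total count over the genes
in the matrix (reads assigned to annotated genes, not total sequenced reads)
and ``L_g`` the gene length in base pairs. Region-level expression is the
arithmetic mean of FPKM over a region's replicates.

A gene is *expressed* in a region when its region-mean FPKM reaches the
expressed threshold (inclusive, default 1). The *retained* set — the analysis
universe for specificity and differential testing — keeps genes whose
expression strictly exceeds the retention threshold, either on the per-region
mean (default rule) or in every replicate of at least one region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DataFormatError, check_samples_match, region_order

__all__ = [
    "QuantifyParams",
    "compute_fpkm",
    "region_means",
    "expressed_sets",
    "ExpressedSummary",
    "retain_genes",
]


@dataclass
class QuantifyParams:
    expressed_threshold: float = 1.0  # inclusive (>=)
    retention_threshold: float = 1.0  # strict (>)
    retention_rule: str = "mean_per_region_any"

    def __post_init__(self) -> None:
        if self.expressed_threshold < 0 or self.retention_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if self.retention_rule not in ("mean_per_region_any", "all_replicates_any_region"):
            raise ValueError(f"unknown retention rule {self.retention_rule!r}")


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase per million mapped fragments, per gene and sample."""
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise DataFormatError(f"gene {missing[0]!r} has no length entry")
    L = lengths.loc[counts.index].to_numpy(dtype=float)
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    zero = counts.columns[totals == 0]
    if len(zero):
        raise DataFormatError(f"sample {zero[0]!r} has zero total counts")
    values = counts.to_numpy(dtype=float) * 1e9 / (totals[None, :] * L[:, None])
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def region_means(fpkm: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Mean FPKM per gene per region, columns in sample-sheet region order."""
    check_samples_match(fpkm, samples)
    regions = region_order(samples.loc[fpkm.columns])
    cols = {}
    for r in regions:
        members = [s for s in fpkm.columns if samples.at[s, "region"] == r]
        cols[r] = fpkm[members].mean(axis=1)
    out = pd.DataFrame(cols)[regions]
    out.index.name = "gene_id"
    return out


@dataclass
class ExpressedSummary:
    """Per-region expressed-gene sets with the shared/unique decomposition."""

    expressed: dict[str, set[str]]
    shared: set[str]
    unique: dict[str, set[str]]

    @property
    def counts(self) -> dict[str, int]:
        return {r: len(s) for r, s in self.expressed.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region": r,
                "n_expressed": len(self.expressed[r]),
                "n_unique": len(self.unique[r]),
            }
            for r in self.expressed
        ]
        df = pd.DataFrame(rows)
        df["n_shared_all_regions"] = len(self.shared)
        return df


def expressed_sets(
    region_expr: pd.DataFrame, params: QuantifyParams | None = None
) -> ExpressedSummary:
    """Expressed genes per region, genes shared by all regions, and genes
    uniquely expressed in a single region."""
    params = params or QuantifyParams()
    thr = params.expressed_threshold
    expressed = {
        r: set(region_expr.index[region_expr[r] >= thr]) for r in region_expr.columns
    }
    sets = list(expressed.values())
    shared = set.intersection(*sets) if sets else set()
    unique = {}
    for r in region_expr.columns:
        others = set().union(*(expressed[o] for o in region_expr.columns if o != r))
        unique[r] = expressed[r] - others
    return ExpressedSummary(expressed=expressed, shared=shared, unique=unique)


def retain_genes(
    region_expr: pd.DataFrame,
    fpkm: pd.DataFrame,
    samples: pd.DataFrame,
    params: QuantifyParams | None = None,
) -> list[str]:
    """Genes kept for downstream analysis, in input gene order.

    ``mean_per_region_any``: keep a gene if its region-mean FPKM strictly
    exceeds the retention threshold in at least one region.
    ``all_replicates_any_region``: keep it if there is a region where every
    replicate individually exceeds the threshold.
    """
    params = params or QuantifyParams()
    thr = params.retention_threshold
    if params.retention_rule == "mean_per_region_any":
        keep = (region_expr > thr).any(axis=1)
        return list(region_expr.index[keep])
    check_samples_match(fpkm, samples)
    keep_mask = np.zeros(len(fpkm.index), dtype=bool)
    for r in region_order(samples.loc[fpkm.columns]):
        members = [s for s in fpkm.columns if samples.at[s, "region"] == r]
        keep_mask |= (fpkm[members] > thr).all(axis=1).to_numpy()
    return list(fpkm.index[keep_mask])
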