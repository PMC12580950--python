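"""All-pairs differential expression with a transparent NB-Wald test.

Every unordered pair of regions is compared (15 comparisons for the
six-region design). Counts are normalised with median-of-ratios size factors;
per gene the test contrasts the two group means of normalised counts with a
Wald statistic under a negative-binomial variance model,

    z = (ln muA - ln muB) / SE,
    SE^2 = (1/muA + alpha) / nA + (1/muB + alpha) / nB,

with alpha a pooled method-of-moments dispersion, two-sided normal p-values
and Benjamini-Hochberg correction within each comparison. A gene is called
up (down) in A versus B when q < fdr_threshold and log2 fold change exceeds
(falls below minus) lfc_threshold; the fold change uses a pseudocount in both
group means so that it stays finite when one group is all zero.

This is a deliberately simple, fully specified test for count data — it is
not a reimplementation of any external differential-expression package, and
its formulas are stated so results can be reproduced line by line.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import check_samples_match

__all__ = [
    "DEParams",
    "enumerate_comparisons",
    "size_factors",
    "pairwise_de",
    "summarize_de",
    "PAPER_COMPARISON_ORDER",
]

# Conventional ordering of the 15 comparisons for the default six cuts.
PAPER_COMPARISON_ORDER = [
    ("BB", "GM"), ("IM", "GM"), ("IM", "BB"),
    ("T", "GM"), ("T", "BB"), ("T", "IM"),
    ("QF", "GM"), ("QF", "BB"), ("QF", "IM"), ("QF", "T"),
    ("LD", "GM"), ("LD", "BB"), ("LD", "IM"), ("LD", "T"), ("LD", "QF"),
]


@dataclass
class DEParams:
    fdr_threshold: float = 0.05
    lfc_threshold: float = 1.0  # on |log2 fold change|
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.fdr_threshold <= 0 or self.lfc_threshold <= 0 or self.pseudocount <= 0:
            raise ValueError("DE thresholds must be positive")


def enumerate_comparisons(regions) -> list[tuple[str, str]]:
    """All C(n, 2) unordered region pairs.

    For the default six cuts the conventional published ordering is used;
    any other label set falls back to combination order over the input.
    """
    regions = list(regions)
    if len(regions) < 2:
        raise ValueError("need at least 2 regions to compare")
    if len(set(regions)) != len(regions):
        raise ValueError("region labels must be unique")
    if set(regions) == {"LD", "IM", "T", "BB", "GM", "QF"}:
        return list(PAPER_COMPARISON_ORDER)
    return list(itertools.combinations(regions, 2))


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors.

    The reference is the per-gene geometric mean over samples, restricted to
    genes with no zero count; each sample's factor is the median ratio of its
    counts to the reference.
    """
    arr = counts.to_numpy(dtype=float)
    usable = (arr > 0).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no gene has positive counts in every sample; cannot form the "
            "median-of-ratios reference"
        )
    logs = np.log(arr[usable])
    ref = np.exp(logs.mean(axis=1))
    factors = np.median(arr[usable] / ref[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _group_stats(norm: np.ndarray, idx: np.ndarray):
    sub = norm[:, idx]
    return sub.mean(axis=1), sub.var(axis=1, ddof=1)


def pairwise_de(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    pair: tuple[str, str],
    params: DEParams | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """NB-Wald differential expression for one region pair (A over B).

    Size factors are computed on the two groups' samples only. Genes with
    both group means zero get p = 1 and log2fc = 0 by convention; a group
    mean of exactly zero enters the Wald statistic at the pseudocount so the
    statistic stays finite.
    """
    params = params or DEParams()
    region_a, region_b = pair
    check_samples_match(counts, samples)
    if genes is not None:
        counts = counts.loc[genes]
    cols_a = [s for s in counts.columns if samples.at[s, "region"] == region_a]
    cols_b = [s for s in counts.columns if samples.at[s, "region"] == region_b]
    for r, cols in ((region_a, cols_a), (region_b, cols_b)):
        if len(cols) < 2:
            raise ValueError(f"region {r!r} has fewer than 2 samples")

    sub = counts[cols_a + cols_b]
    sf = size_factors(sub)
    norm = sub.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    n_a, n_b = len(cols_a), len(cols_b)
    mu_a, v_a = _group_stats(norm, np.arange(n_a))
    mu_b, v_b = _group_stats(norm, np.arange(n_a, n_a + n_b))

    # pooled method-of-moments dispersion: within-group variance against the
    # average of the two group means, truncated at zero (Poisson floor)
    v_pool = ((n_a - 1) * v_a + (n_b - 1) * v_b) / (n_a + n_b - 2)
    mu_bar = (mu_a + mu_b) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mu_bar > 0, (v_pool - mu_bar) / mu_bar**2, 0.0)
    alpha = np.maximum(alpha, 0.0)

    pc = params.pseudocount
    log2fc = np.log2((mu_a + pc) / (mu_b + pc))

    both_zero = (mu_a == 0) & (mu_b == 0)
    ma = np.where(mu_a > 0, mu_a, pc)
    mb = np.where(mu_b > 0, mu_b, pc)
    se = np.sqrt((1.0 / ma + alpha) / n_a + (1.0 / mb + alpha) / n_b)
    z = (np.log(ma) - np.log(mb)) / se
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue = np.where(both_zero, 1.0, pvalue)
    log2fc = np.where(both_zero, 0.0, log2fc)
    z = np.where(both_zero, 0.0, z)

    qvalue = multipletests(pvalue, method="fdr_bh")[1]
    sig = qvalue < params.fdr_threshold
    direction = np.where(
        sig & (log2fc > params.lfc_threshold),
        "up",
        np.where(sig & (log2fc < -params.lfc_threshold), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "comparison": f"{region_a}_vs_{region_b}",
            "gene_id": sub.index,
            "log2fc": log2fc,
            "stat": z,
            "pvalue": pvalue,
            "qvalue": qvalue,
            "direction": direction,
        }
    )


def summarize_de(records: pd.DataFrame) -> pd.DataFrame:
    """Per-comparison totals of up/down differentially expressed genes.

    ``records`` is the concatenation of :func:`pairwise_de` outputs; the
    summary preserves each comparison's first appearance order.
    """
    if records.empty:
        raise ValueError("no differential-expression records to summarise")
    order = list(dict.fromkeys(records["comparison"]))
    rows = []
    for comp in order:
        sub = records[records["comparison"] == comp]
        n_up = int((sub["direction"] == "up").sum())
        n_down = int((sub["direction"] == "down").sum())
        rows.append(
            {"comparison": comp, "n_up": n_up, "n_down": n_down, "n_total": n_up + n_down}
        )
    return pd.DataFrame(rows)
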