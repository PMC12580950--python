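"""Gene-panel expression comparison across regions.

Panels are named gene sets (fatty-acid biosynthesis, degradation and
elongation, and muscle-fiber structure by default). For each panel gene the
module reports per-region mean FPKM, the coefficient of variation of the
region means, and a Kruskal-Wallis test on the replicate-level FPKM across
regions with Benjamini-Hochberg correction within the panel. A gene is
classed ``variable`` when its adjusted p-value falls below the threshold and
``stable`` otherwise, turning the qualitative question "does this panel vary
between cuts?" into an explicit statistic.

Default panels carry gene symbols; mapping symbols to the gene ids of a
particular annotation is the caller's responsibility, and panel genes absent
from the expression matrix are reported with ``missing=True`` rather than
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import check_samples_match, region_order

__all__ = ["PanelDefinition", "default_panels", "panel_summary", "read_panels", "write_panels"]


@dataclass
class PanelDefinition:
    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"panel {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            seen = set()
            dup = next(g for g in self.genes if g in seen or seen.add(g))
            raise ValueError(f"panel {self.name!r} lists gene {dup!r} twice")


_FA_BIOSYNTHESIS = [
    "SAST", "OXSM", "IQCAL", "IQCA1", "FAS", "FABD", "CCD57",
    "ACSL1", "ACSL3", "ACSL4", "ACSL5", "ACSL6", "ACBG1", "ACBG2", "ACAC",
]
_FA_DEGRADATION = [
    "THIM", "THIL", "THIK", "THIC", "SPAT9", "GNB1L", "GCDH", "ECI",
    "ECHP", "ECHM", "ECHA", "ECHB", "CPT2", "CPT1A", "CPT1B", "CPT1C",
    "CP4CA", "CP4AO", "CP4AB", "AL9A1", "AL7A1", "AL3A2", "ADH", "ACSL1",
    "ACOXL", "ACOX1", "ACOX3", "ACDSB", "ACBG2", "ACBG1", "ACADV", "ACADS",
    "A16A1",
]
_FA_ELONGATION = [
    "THIM", "TECRL", "TECR", "SLMAP", "PPT1", "PPT2", "MECR", "HSDL1",
    "HACD", "ELOV", "ECHM", "ECHB", "ECHA", "DHB12", "BACH", "ACOT1",
    "ACOT2", "ACOT4",
]
_MUSCLE_FIBER = ["TPM1", "MYH1", "MYL6B", "TNNI1"]


def default_panels() -> list[PanelDefinition]:
    """The four built-in panels (gene symbols, not annotation-specific ids)."""
    return [
        PanelDefinition("fatty_acid_biosynthesis", list(_FA_BIOSYNTHESIS)),
        PanelDefinition("fatty_acid_degradation", list(_FA_DEGRADATION)),
        PanelDefinition("fatty_acid_elongation", list(_FA_ELONGATION)),
        PanelDefinition("muscle_fiber_structure", list(_MUSCLE_FIBER)),
    ]


def read_panels(path) -> list[PanelDefinition]:
    """Read a panels TSV with columns panel_name, gene_id."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    panels = []
    for name in dict.fromkeys(table["panel_name"]):
        genes = table.loc[table["panel_name"] == name, "gene_id"].tolist()
        panels.append(PanelDefinition(name, genes))
    return panels


def write_panels(panels: list[PanelDefinition], path) -> None:
    rows = [(p.name, g) for p in panels for g in p.genes]
    pd.DataFrame(rows, columns=["panel_name", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def _kruskal(groups: list[np.ndarray]) -> tuple[float, float]:
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        # all observations identical: the regions are indistinguishable
        return 0.0, 1.0
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)


def panel_summary(
    fpkm: pd.DataFrame,
    samples: pd.DataFrame,
    panels: list[PanelDefinition] | None = None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene region means, CV and Kruskal-Wallis classification per panel.

    Returns a tidy frame with one row per (panel, gene): ``mean_<region>``
    columns, ``cv`` (sd over mean of the region means; 0 with the degenerate
    flag when the mean is 0), the Kruskal-Wallis statistic and p-value on
    replicate FPKM (midrank ties, chi-square approximation), the BH-adjusted
    q-value within the panel, and class ``stable`` / ``variable`` / ``missing``.
    """
    if panels is None:
        panels = default_panels()
    if not panels:
        raise ValueError("no panels given")
    check_samples_match(fpkm, samples)
    regions = region_order(samples.loc[fpkm.columns])
    groups_cols = {
        r: [s for s in fpkm.columns if samples.at[s, "region"] == r] for r in regions
    }

    rows = []
    for panel in panels:
        present, stats_rows = [], []
        for gene in panel.genes:
            row: dict = {"panel": panel.name, "gene_id": gene}
            if gene not in fpkm.index:
                row.update(
                    {f"mean_{r}": np.nan for r in regions},
                    cv=np.nan, kw_stat=np.nan, kw_pvalue=np.nan, qvalue=np.nan,
                    missing=True, gene_class="missing",
                )
                rows.append(row)
                continue
            reps = [fpkm.loc[gene, groups_cols[r]].to_numpy(dtype=float) for r in regions]
            means = np.array([g.mean() for g in reps])
            for r, m in zip(regions, means):
                row[f"mean_{r}"] = m
            grand = means.mean()
            row["cv"] = float(means.std(ddof=1) / grand) if grand > 0 else 0.0
            stat, p = _kruskal(reps)
            row["kw_stat"] = stat
            row["kw_pvalue"] = p
            row["missing"] = False
            rows.append(row)
            present.append(row)
        # BH within the panel, over genes actually measured
        if present:
            pvals = np.array([r["kw_pvalue"] for r in present])
            qvals = multipletests(pvals, method="fdr_bh")[1]
            for r, q in zip(present, qvals):
                r["qvalue"] = float(q)
                r["gene_class"] = "variable" if q < q_threshold else "stable"
    return pd.DataFrame(rows)
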