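"""End-to-end orchestration: simulate -> quantify -> detect -> test -> panels.

A single :class:`RunConfig` (loadable from YAML) holds the per-stage parameter
blocks and one seed; :func:`run_all` writes every stage's tables plus a run
summary JSON that echoes the effective parameters, so a run is fully described
by its config and reproducible from it. Identical config and seed give
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .de import DEParams, enumerate_comparisons, pairwise_de, summarize_de
from .panels import PanelDefinition, default_panels, panel_summary, read_panels, write_panels
from .quantify import QuantifyParams, compute_fpkm, expressed_sets, region_means, retain_genes
from .rsg import RSGParams, cluster_rsg, detect_rsg, rsg_calls_to_list
from .simulate import SimulationConfig, simulate_dataset, truth_eval, write_truth

__all__ = ["RunConfig", "run_all", "run_quantify", "run_rsg", "run_de", "run_panels"]

log = logging.getLogger("cutspec")


@dataclass
class RunConfig:
    out_dir: Path = Path("cutspec_run")
    seed: int = 0
    counts: Path | None = None  # when None, data are simulated
    samples: Path | None = None
    lengths: Path | None = None
    panels_file: Path | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    quantify: QuantifyParams = field(default_factory=QuantifyParams)
    rsg: RSGParams = field(default_factory=RSGParams)
    de: DEParams = field(default_factory=DEParams)
    panel_q_threshold: float = 0.05
    force: bool = False

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in ("out_dir", "counts", "samples", "lengths", "panels_file"):
            if key in raw:
                setattr(cfg, key, Path(raw[key]))
        for key in ("seed", "panel_q_threshold", "force"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "simulation" in raw:
            cfg.simulation = SimulationConfig(**raw["simulation"])
        if "quantify" in raw:
            cfg.quantify = QuantifyParams(**raw["quantify"])
        if "rsg" in raw:
            cfg.rsg = RSGParams(**raw["rsg"])
        if "de" in raw:
            cfg.de = DEParams(**raw["de"])
        for key, val in overrides.items():
            if val is not None:
                setattr(cfg, key, val)
        return cfg

    def params_echo(self) -> dict:
        return {
            "seed": self.seed,
            "simulation": self.simulation.to_dict(),
            "quantify": vars(self.quantify).copy(),
            "rsg": vars(self.rsg).copy(),
            "de": vars(self.de).copy(),
            "panel_q_threshold": self.panel_q_threshold,
        }


def _prepare_out(out_dir: Path, force: bool) -> Path:
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out_dir} is not empty; pass force=True/--force to overwrite"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    return out_dir


def run_quantify(counts, samples, lengths, params: QuantifyParams):
    fpkm = compute_fpkm(counts, lengths)
    rmeans = region_means(fpkm, samples)
    summary = expressed_sets(rmeans, params)
    retained = retain_genes(rmeans, fpkm, samples, params)
    return fpkm, rmeans, summary, retained


def run_rsg(rmeans, retained, params: RSGParams):
    calls = detect_rsg(rmeans, retained, params)
    hits = rsg_calls_to_list(calls)
    clustering = None
    if len(hits) >= 2:
        clustering = cluster_rsg(rmeans.loc[hits["gene_id"]])
    return calls, hits, clustering


def run_de(counts, samples, retained, params: DEParams):
    regions = cio.region_order(samples.loc[counts.columns])
    pairs = enumerate_comparisons(regions)
    records = pd.concat(
        [pairwise_de(counts, samples, pair, params, genes=retained) for pair in pairs],
        ignore_index=True,
    )
    return pairs, records, summarize_de(records)


def run_panels(fpkm, samples, panels, q_threshold):
    return panel_summary(fpkm, samples, panels, q_threshold=q_threshold)


def run_all(config: RunConfig) -> dict:
    """Run every stage, write all outputs under config.out_dir, return the summary."""
    out = _prepare_out(config.out_dir, config.force)
    log.info("run seed=%d out_dir=%s", config.seed, out)

    truth = None
    if config.counts is None:
        sim_cfg = config.simulation
        sim_cfg.seed = config.seed
        counts, samples, lengths, truth = simulate_dataset(sim_cfg)
        cio.write_counts(counts, out / "counts.tsv")
        cio.write_sample_sheet(samples, out / "samples.csv")
        cio.write_gene_lengths(lengths, out / "gene_lengths.tsv")
        write_truth(truth, out / "truth.tsv")
    else:
        counts = cio.read_counts(config.counts)
        samples = cio.read_sample_sheet(config.samples)
        lengths = cio.read_gene_lengths(config.lengths)

    fpkm, rmeans, expr_summary, retained = run_quantify(
        counts, samples, lengths, config.quantify
    )
    cio.write_matrix(fpkm, out / "fpkm.tsv")
    cio.write_matrix(rmeans, out / "region_means.tsv")
    expr_summary.to_frame().to_csv(out / "expressed_summary.tsv", sep="\t", index=False)
    cio.write_gene_list(retained, out / "retained_genes.tsv")

    calls, hits, clustering = run_rsg(rmeans, retained, config.rsg)
    calls.to_csv(out / "rsg_calls.tsv", sep="\t", index=False)
    hits.to_csv(out / "rsg_list.tsv", sep="\t", index=False)
    if clustering is not None:
        cio.write_matrix(clustering.zscores, out / "rsg_heatmap_matrix.tsv")
        with open(out / "rsg_dendrogram.json", "w") as fh:
            json.dump(clustering.to_json_dict(), fh, indent=1)

    pairs, de_records, de_summary = run_de(counts, samples, retained, config.de)
    for pair in pairs:
        comp = f"{pair[0]}_vs_{pair[1]}"
        de_records[de_records["comparison"] == comp].to_csv(
            out / f"de_{comp}.tsv", sep="\t", index=False
        )
    de_summary.to_csv(out / "de_summary.tsv", sep="\t", index=False)

    if config.panels_file is not None:
        panels = read_panels(config.panels_file)
    else:
        panels = default_panels()
    write_panels(panels, out / "panels.tsv")
    psum = run_panels(fpkm, samples, panels, config.panel_q_threshold)
    psum.to_csv(out / "panel_summary.tsv", sep="\t", index=False)

    regions = cio.region_order(samples)
    rsg_per_region = {
        r: int((hits["region"] == r).sum()) for r in regions
    }
    summary = {
        "seed": config.seed,
        "parameters": config.params_echo(),
        "n_genes": int(counts.shape[0]),
        "n_samples": int(counts.shape[1]),
        "n_regions": len(regions),
        "regions": regions,
        "expressed_per_region": {r: len(expr_summary.expressed[r]) for r in regions},
        "n_shared_all_regions": len(expr_summary.shared),
        "unique_per_region": {r: len(expr_summary.unique[r]) for r in regions},
        "n_retained": len(retained),
        "n_rsg_total": int(len(hits)),
        "rsg_per_region": rsg_per_region,
        "n_comparisons": len(pairs),
        "deg_per_comparison": {
            row["comparison"]: {"up": row["n_up"], "down": row["n_down"], "total": row["n_total"]}
            for _, row in de_summary.iterrows()
        },
        "panel_classes": {
            p: sub["gene_class"].value_counts().to_dict()
            for p, sub in psum.groupby("panel", sort=False)
        },
    }
    if truth is not None:
        predicted = list(zip(hits["gene_id"], hits["region"]))
        summary["truth_recovery"] = truth_eval(predicted, truth)
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
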