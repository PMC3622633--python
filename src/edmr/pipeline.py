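"""End-to-end DMR calling: cutoff fit -> segmentation -> filters ->
dependence-adjusted significance -> FDR -> annotation -> summaries.

The stage order is fixed and every stage logs its input/output counts; a
rerun with identical inputs and configuration produces bit-identical output
files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import annotation as ann
from . import gap_model, io, regions, significance, summaries

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunables of the DMR pipeline.

    ``dist_cutoff=None`` fits the gap mixture and optimizes the cutoff;
    an integer fixes the segmentation distance and skips fitting.
    """

    dist_cutoff: int | None = None
    min_dmcs: int = 1
    min_cpgs: int = 3
    min_abs_mean_diff: float = 20.0
    dmc_qvalue: float = 0.01
    dmc_diff: float = 25.0
    bin_size: int = 100
    max_lag: int = 10
    acf_source: str = "pvalue"
    combine: str = "all"
    fdr: float = 0.05
    promoter_up: int = 1000
    promoter_down: int = 1000
    shore_width: int = 2000
    min_gap_sample: int = 500
    seed: int = 0
    plots: bool = False

    def validate(self) -> None:
        if self.dist_cutoff is not None and self.dist_cutoff < 1:
            raise ValueError("dist_cutoff must be >= 1")
        if self.acf_source not in ("pvalue", "meth_diff"):
            raise ValueError(f"invalid acf_source {self.acf_source!r}")
        if self.combine not in ("all", "dmc-only"):
            raise ValueError(f"invalid combine mode {self.combine!r}")
        for name in ("min_dmcs", "min_cpgs", "bin_size", "max_lag",
                     "promoter_up", "promoter_down", "shore_width", "min_gap_sample"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("dmc_qvalue", "fdr"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


def run_pipeline(cpgs: pd.DataFrame, config: RunConfig, outdir,
                 tracks: Sequence[ann.FeatureTrack] | None = None) -> dict:
    """Run the full workflow on a per-CpG frame and write all outputs.

    Writes ``dmr.tsv``, ``dmr.bed``, ``fit.json``, ``acf.tsv``,
    ``summary.tsv`` and ``edmr.log`` (plus ``annotation.tsv`` /
    ``annotation_counts.tsv`` when tracks are given) into ``outdir`` and
    returns a dict with the key stage counts and in-memory results.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines: list[str] = []

    def stage(msg: str) -> None:
        log.info(msg)
        lines.append(msg)

    stage(f"input: {len(cpgs)} CpGs on {cpgs['chrom'].nunique()} chromosomes")

    # 1. distance cutoff
    fit_info: dict = {}
    if config.dist_cutoff is not None:
        dist_cutoff = int(config.dist_cutoff)
        fit_info = {"dist_cutoff": dist_cutoff, "source": "user-override"}
        stage(f"cutoff: user override D={dist_cutoff} bp (mixture fit skipped)")
    else:
        sample = gap_model.compute_gap_sample(cpgs, min_size=config.min_gap_sample)
        fit = gap_model.fit_bimodal_em(sample, seed=config.seed)
        cutoff = gap_model.optimize_cutoff(fit, sample)
        dist_cutoff = cutoff.D
        fit_info = {
            "dist_cutoff": cutoff.D, "source": "mixture-fit",
            "x_hat": cutoff.x_hat, "cost_at_min": cutoff.cost_at_min,
            "n_gaps": int(sample.values.size),
            "n_removed_spike": sample.n_removed_spike,
            "fit": dataclasses.asdict(fit),
        }
        stage(
            f"cutoff: fitted mixture on {sample.values.size} gaps "
            f"({sample.n_removed_spike} removed at 1-bp spike); "
            f"x_hat={cutoff.x_hat:.4f}, D={cutoff.D} bp"
        )
        if config.plots:
            gap_model.plot_gap_fit(sample, fit, cutoff, outdir / "gap_fit.png")
    (outdir / "fit.json").write_text(json.dumps(fit_info, indent=2, sort_keys=True))

    # 2. segmentation + filters
    labelled = regions.segment_regions(cpgs, dist_cutoff)
    raw_regions = regions.summarize_regions(labelled, config.dmc_qvalue, config.dmc_diff)
    stage(f"segmentation: {len(raw_regions)} raw regions at D={dist_cutoff}")
    candidates = regions.filter_regions(
        raw_regions, config.min_dmcs, config.min_cpgs, config.min_abs_mean_diff
    )
    stage(
        f"filters: {len(candidates)} regions pass "
        f"(dmcs>={config.min_dmcs}, cpgs>={config.min_cpgs}, "
        f"|mean diff|>{config.min_abs_mean_diff})"
    )

    # 3. significance
    acf = significance.estimate_acf(cpgs, config.bin_size, config.max_lag, config.acf_source)
    acf_diag = significance.estimate_acf(
        cpgs, config.bin_size, config.max_lag,
        "meth_diff" if config.acf_source == "pvalue" else "pvalue",
    )
    acf_by_source = {acf.source: acf, acf_diag.source: acf_diag}
    pd.DataFrame({
        "lag": acf.lags,
        "rho_pvalue": acf_by_source["pvalue"].rho,
        "rho_meth_diff": acf_by_source["meth_diff"].rho,
    }).to_csv(outdir / "acf.tsv", sep="\t", index=False)
    dmrs = significance.assign_significance(
        candidates, labelled, acf, config.combine, config.dmc_qvalue, config.dmc_diff
    )
    n_sig = int((dmrs["q_value"] < config.fdr).sum()) if len(dmrs) else 0
    stage(f"significance: {len(dmrs)} DMRs combined; {n_sig} at q<{config.fdr}")
    if dmrs.empty:
        stage("warning: no regions survive the filters; outputs are empty")

    dmr_out = dmrs.drop(columns=["region_id"]) if "region_id" in dmrs else dmrs
    io.write_dmr_output(dmr_out, outdir / "dmr.tsv", "tsv")
    io.write_dmr_output(dmr_out, outdir / "dmr.bed", "bed")

    # 4. annotation (optional)
    ann_counts = None
    if tracks:
        rows, ann_counts = ann.annotate_dmrs(dmr_out.reset_index(drop=True), tracks)
        rows.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        ann_counts.to_csv(outdir / "annotation_counts.tsv", sep="\t", index=False)
        stage(f"annotation: {len(rows)} overlap rows over {len(tracks)} tracks")

    # 5. summaries
    summary = summaries.summarize_dmrs(dmr_out)
    summaries.summary_frame(summary).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    stage(
        f"summary: {summary.n_dmrs} DMRs ({summary.n_hyper} hyper / {summary.n_hypo} hypo)"
    )
    if config.plots and summary.n_dmrs:
        summaries.plot_summary(dmr_out, outdir / "summary.png")

    (outdir / "edmr.log").write_text("\n".join(lines) + "\n")
    return {
        "dist_cutoff": dist_cutoff,
        "fit_info": fit_info,
        "n_cpgs": len(cpgs),
        "n_raw_regions": len(raw_regions),
        "n_candidates": len(candidates),
        "n_dmrs": len(dmrs),
        "n_significant": n_sig,
        "dmrs": dmr_out,
        "acf": acf,
        "annotation_counts": ann_counts,
        "outdir": outdir,
    }


def load_tracks(genes=None, cpg_islands=None, user_tracks=None,
                promoter_up: int = 1000, promoter_down: int = 1000,
                shore_width: int = 2000, strip_chr: bool = False) -> list[ann.FeatureTrack]:
    """Assemble annotation tracks from refFlat/BED inputs.

    ``user_tracks`` is an iterable of (name, path) pairs.
    """
    tracks: list[ann.FeatureTrack] = []
    if genes is not None:
        models = io.read_gene_model(genes, strip_chr=strip_chr)
        parts = ann.derive_gene_parts(models, promoter_up, promoter_down)
        tracks.extend(parts[name] for name in ann.GENE_PART_NAMES)
    if cpg_islands is not None:
        islands = io.read_interval_track(cpg_islands, "cpg_island", strip_chr=strip_chr)
        tracks.append(islands)
        tracks.append(ann.derive_shores(islands, shore_width))
    for name, path in user_tracks or []:
        tracks.append(io.read_interval_track(path, name, strip_chr=strip_chr))
    return tracks
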