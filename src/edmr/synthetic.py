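"""Seeded synthetic per-CpG differential-methylation datasets with known truth.

The generator emulates the data-generating structure an enrichment bisulfite
experiment produces:

* CpG positions whose adjacent-gap log2 distribution is a two-component
  normal mixture (regional vs boundary gaps), plus a 1-bp opposite-strand
  spike from non-destranded CpG/GpC pairs;
* planted DMRs: runs of consecutive CpGs with an elevated methylation
  difference of a common sign. Interior gaps of a planted run are drawn from
  the regional component and the two flanking gaps from the boundary
  component, reflecting that a DMR is a CpG cluster bounded by large gaps;
* spatially autocorrelated p-values: a latent z per 100-bp bin follows an
  AR(1) chain along each chromosome, and each CpG observes
  sqrt(w)*z_bin + sqrt(1-w)*noise (marginally standard normal, so null
  p-values are uniform); CpGs in planted DMRs receive an additional mean
  shift so that effect size and significance are coherent.

Everything is driven by one integer seed; identical config + seed gives
bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import lfilter
from scipy.stats import norm

from .io import write_dmc_table
from .significance import bh_fdr


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Gap-mixture defaults place the weighted-density crossing near
    log2(183) ~ 7.5, i.e. a boundary cutoff of roughly 180 bp, typical of
    enrichment bisulfite data. The p-value field uses a strong short-range
    spatial autocorrelation (AR(1) rho = 0.7 across 100-bp bins, within-bin
    share 0.9), consistent with the high lag-1 autocorrelation reported for
    differential-methylation p-values at this scale.
    """

    seed: int = 0
    n_cpgs: int = 200_000
    chroms: tuple[str, ...] = ("chr1", "chr2", "chr3", "chr4")
    # gap mixture on the log2 scale
    lambda1: float = 0.85
    mu1: float = 4.66
    sigma1: float = 1.2
    mu2: float = 9.5
    sigma2: float = 1.5
    spike_fraction: float = 0.10
    # planted DMRs
    n_dmrs: int = 50
    cpgs_per_dmr: int = 10
    effect: float = 40.0
    noise_sd: float = 5.0
    alt_z_shift: float = 8.0
    # spatial p-value model
    ar1_coef: float = 0.7
    bin_size: int = 100
    bin_share: float = 0.9
    # read depth (>= 10x, as after standard coverage filtering)
    coverage_mean: float = 79.0
    coverage_shape: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.lambda1 < 1:
            raise ValueError("lambda1 must lie in (0, 1)")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must lie in [0, 1)")
        if not 0 < self.effect <= 100 and self.n_dmrs > 0:
            raise ValueError("effect must lie in (0, 100]")
        if not 0 <= self.bin_share <= 1:
            raise ValueError("bin_share must lie in [0, 1]")

    @property
    def lambda2(self) -> float:
        return 1.0 - self.lambda1

    def x_star(self) -> float:
        """True weighted-density crossing of the two gap components."""
        def g(x):
            return self.lambda2 * norm.pdf(x, self.mu2, self.sigma2) - self.lambda1 * norm.pdf(
                x, self.mu1, self.sigma1
            )
        return float(brentq(g, self.mu1, self.mu2, xtol=1e-12))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class SyntheticTruth:
    """Ground truth: planted intervals, gap crossing point, per-CpG labels."""

    dmrs: pd.DataFrame  # chrom, start, end, direction
    x_star: float
    dmr_id: np.ndarray  # per CpG row of the generated frame; -1 for null CpGs
    config: SyntheticConfig = field(repr=False)


def _ar1_series(n: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) chain with unit marginal variance."""
    w = rng.standard_normal(n)
    if n == 0 or rho == 0.0:
        return w
    w[1:] *= np.sqrt(1.0 - rho * rho)
    return lfilter([1.0], [1.0, -rho], w)


def _plant_runs(n: int, k: int, run_len: int, margin: int,
                rng: np.random.Generator) -> np.ndarray:
    """k non-overlapping run start indices, >= margin apart and off the edges."""
    if k == 0:
        return np.empty(0, dtype=int)
    slot = run_len + margin
    free = n - 2 * margin - k * slot
    if free < 0:
        raise ValueError(f"cannot place {k} runs of {run_len} CpGs in {n}")
    offsets = np.sort(rng.choice(free + 1, size=k, replace=True))
    return margin + offsets + np.arange(k) * slot


def generate_positions(config: SyntheticConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[pd.DataFrame, np.ndarray]:
    """CpG positions plus the per-row planted-DMR id (-1 = null).

    Gaps are ``max(2, round(2**x))`` with x drawn from the log2 mixture;
    ``spike_fraction`` of the CpGs are duplicated at +1 bp on the opposite
    strand, emulating non-destranded input.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    x_star = config.x_star()
    n_chrom = len(config.chroms)
    counts = [config.n_cpgs // n_chrom] * n_chrom
    counts[0] += config.n_cpgs - sum(counts)
    dmr_counts = [config.n_dmrs // n_chrom] * n_chrom
    dmr_counts[0] += config.n_dmrs - sum(dmr_counts)

    frames = []
    next_dmr = 0
    for chrom, n_c, k_c in zip(config.chroms, counts, dmr_counts):
        starts = _plant_runs(n_c, k_c, config.cpgs_per_dmr, margin=10, rng=rng)
        dmr_id = np.full(n_c, -1, dtype=int)
        for s in starts:
            dmr_id[s:s + config.cpgs_per_dmr] = next_dmr
            next_dmr += 1
        # gap i sits between CpG i and CpG i+1
        comp = (rng.random(n_c - 1) >= config.lambda1).astype(int)
        interior = (dmr_id[:-1] >= 0) & (dmr_id[:-1] == dmr_id[1:])
        comp[interior] = 0
        flank = (dmr_id[:-1] != dmr_id[1:]) & ((dmr_id[:-1] >= 0) | (dmr_id[1:] >= 0))
        comp[flank] = 1
        mu = np.where(comp == 0, config.mu1, config.mu2)
        sigma = np.where(comp == 0, config.sigma1, config.sigma2)
        x = rng.normal(mu, sigma)
        # flanking gaps of planted runs: boundary component conditioned on
        # exceeding the crossing point, so planted truth intervals are
        # genuinely separated from neighbouring null clusters
        if flank.any():
            floor = (x_star + 0.1 - config.mu2) / config.sigma2
            u = rng.uniform(norm.cdf(floor), 1.0, size=int(flank.sum()))
            x[flank] = config.mu2 + config.sigma2 * norm.ppf(u)
        gaps = np.maximum(2, np.round(2.0**x)).astype(np.int64)
        pos = np.empty(n_c, dtype=np.int64)
        pos[0] = 1000
        np.cumsum(gaps, out=pos[1:])
        pos[1:] += 1000
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "strand": "+",
                                    "dmr_id": dmr_id}))
    df = pd.concat(frames, ignore_index=True)

    n_spike = int(round(config.spike_fraction * len(df)))
    if n_spike:
        idx = rng.choice(len(df), size=n_spike, replace=False)
        dup = df.iloc[idx].copy()
        dup["pos"] += 1
        dup["strand"] = "-"
        df = pd.concat([df, dup], ignore_index=True)
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df[["chrom", "pos", "strand"]], df["dmr_id"].to_numpy()


def generate_methylation(positions: pd.DataFrame, dmr_id: np.ndarray,
                         config: SyntheticConfig,
                         rng: np.random.Generator | None = None
                         ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Methylation differences, p-values and q-values for given positions."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = len(positions)
    z = np.empty(n)
    for chrom, sub in positions.groupby("chrom", sort=False):
        bins = (sub["pos"].to_numpy() - 1) // config.bin_size
        z_bins = _ar1_series(int(bins.max()) + 1, config.ar1_coef, rng)
        eps = rng.standard_normal(len(sub))
        w = config.bin_share
        z[sub.index.to_numpy()] = np.sqrt(w) * z_bins[bins] + np.sqrt(1.0 - w) * eps

    sign = rng.choice([-1.0, 1.0], size=max(config.n_dmrs, 1))
    alt = dmr_id >= 0
    z = z + np.where(alt, config.alt_z_shift, 0.0)
    pvalue = norm.sf(z)

    mean_diff = np.where(alt, sign[np.clip(dmr_id, 0, None)] * config.effect, 0.0)
    meth_diff = np.clip(rng.normal(mean_diff, config.noise_sd), -100.0, 100.0)

    shape = config.coverage_shape
    p_nb = shape / (shape + config.coverage_mean - 10.0)
    coverage = 10 + rng.negative_binomial(shape, p_nb, size=n)

    cpgs = pd.DataFrame({
        "chrom": positions["chrom"].to_numpy(),
        "pos": positions["pos"].to_numpy(),
        "strand": positions["strand"].to_numpy(),
        "coverage": coverage.astype(np.int64),
        "meth_diff": meth_diff,
        "pvalue": pvalue,
        "qvalue": bh_fdr(pvalue),
    })

    truth_rows = []
    for d in range(config.n_dmrs):
        sel = cpgs.loc[dmr_id == d]
        truth_rows.append({
            "chrom": sel["chrom"].iloc[0],
            "start": int(sel["pos"].min()),
            "end": int(sel["pos"].max()),
            "direction": "hyper" if sign[d] > 0 else "hypo",
        })
    truth_dmrs = pd.DataFrame(truth_rows, columns=["chrom", "start", "end", "direction"])
    if not truth_dmrs.empty:
        truth_dmrs = truth_dmrs.sort_values(["chrom", "start"]).reset_index(drop=True)
    return cpgs, SyntheticTruth(truth_dmrs, config.x_star(), dmr_id, config)


def generate_dataset(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Positions + methylation in one call; fully determined by the config."""
    rng = np.random.default_rng(config.seed)
    positions, dmr_id = generate_positions(config, rng)
    return generate_methylation(positions, dmr_id, config, rng)


def write_dataset(cpgs: pd.DataFrame, truth: SyntheticTruth, outdir) -> dict[str, Path]:
    """Write the methyldiff TSV, truth BED and config/truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cpgs": outdir / "cpgs.tsv",
        "truth_bed": outdir / "truth_dmrs.bed",
        "truth_json": outdir / "truth.json",
    }
    write_dmc_table(cpgs, paths["cpgs"])
    with open(paths["truth_bed"], "w") as fh:
        for row in truth.dmrs.itertuples():
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.direction}\t0\t.\n")
    with open(paths["truth_json"], "w") as fh:
        fh.write(json.dumps({"x_star": truth.x_star,
                             "config": dataclasses.asdict(truth.config)},
                            indent=2, sort_keys=True))
    return paths


def recovery_metrics(called: pd.DataFrame, truth: pd.DataFrame,
                     q_threshold: float = 0.05) -> dict[str, float]:
    """Compare called DMRs (at q < threshold) against planted truth.

    Returns sensitivity (fraction of planted DMRs overlapped by >= 1
    significant call), base-level Jaccard of the two interval unions, and
    the fraction of significant calls overlapping no planted DMR.
    """
    from ._intervals import intersect_length, merge_intervals, total_length

    sig = called[called["q_value"] < q_threshold] if len(called) else called
    if truth.empty:
        return {"sensitivity": float("nan"), "jaccard": float("nan"),
                "false_call_rate": 1.0 if len(sig) else 0.0, "n_called": float(len(sig))}
    if sig.empty:
        return {"sensitivity": 0.0, "jaccard": 0.0, "false_call_rate": 0.0, "n_called": 0.0}

    def overlaps_any(row, other) -> bool:
        sub = other[other["chrom"] == row.chrom]
        return bool(((sub["start"] <= row.end) & (sub["end"] >= row.start)).any())

    hit = sum(overlaps_any(t, sig) for t in truth.itertuples())
    false_calls = sum(not overlaps_any(c, truth) for c in sig.itertuples())
    cols = ["chrom", "start", "end"]
    inter = intersect_length(sig[cols], truth[cols])
    union = (total_length(merge_intervals(sig[cols])) + total_length(merge_intervals(truth[cols]))
             - inter)
    return {
        "sensitivity": hit / len(truth),
        "jaccard": inter / union if union else 0.0,
        "false_call_rate": false_calls / len(sig),
        "n_called": float(len(sig)),
    }
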