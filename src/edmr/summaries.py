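"""Whole-methylome DMR descriptive statistics and cross-group comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

QUANTILE_PROBS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class DmrSummary:
    """Counts and {0, .25, .5, .75, 1} quantiles of a DMR set.

    Quantile arrays are ``None`` when the set is empty.
    """

    n_dmrs: int
    n_hyper: int
    n_hypo: int
    length_quantiles: np.ndarray | None
    mean_diff_quantiles: np.ndarray | None
    dmcs_per_dmr_quantiles: np.ndarray | None


def dmr_lengths(dmrs: pd.DataFrame) -> np.ndarray:
    """Inclusive region lengths in bp (end - start + 1)."""
    return (dmrs["end"].to_numpy() - dmrs["start"].to_numpy() + 1).astype(float)


def summarize_dmrs(dmrs: pd.DataFrame) -> DmrSummary:
    """Descriptive summary: hyper/hypo counts and length/effect/DMC quantiles."""
    n = len(dmrs)
    if n == 0:
        return DmrSummary(0, 0, 0, None, None, None)
    n_hyper = int((dmrs["mean_diff"] > 0).sum())
    q = list(QUANTILE_PROBS)
    return DmrSummary(
        n_dmrs=n,
        n_hyper=n_hyper,
        n_hypo=n - n_hyper,
        length_quantiles=np.quantile(dmr_lengths(dmrs), q),
        mean_diff_quantiles=np.quantile(dmrs["mean_diff"].to_numpy(dtype=float), q),
        dmcs_per_dmr_quantiles=np.quantile(dmrs["dmc_count"].to_numpy(dtype=float), q),
    )


def summary_frame(summary: DmrSummary) -> pd.DataFrame:
    """Tidy one-row-per-statistic table for TSV output."""
    rows = [("n_dmrs", summary.n_dmrs), ("n_hyper", summary.n_hyper),
            ("n_hypo", summary.n_hypo)]
    for label, arr in (("length_bp", summary.length_quantiles),
                       ("mean_diff", summary.mean_diff_quantiles),
                       ("dmcs_per_dmr", summary.dmcs_per_dmr_quantiles)):
        if arr is None:
            continue
        for prob, val in zip(QUANTILE_PROBS, arr):
            rows.append((f"{label}_q{int(prob * 100)}", float(val)))
    return pd.DataFrame(rows, columns=["statistic", "value"])


def compare_length_distributions(a: pd.DataFrame, b: pd.DataFrame):
    """Two-sample Kolmogorov-Smirnov test on DMR length vectors.

    Returns the scipy result object (``statistic``, ``pvalue``).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both DMR sets must be non-empty for a KS comparison")
    return ks_2samp(dmr_lengths(a), dmr_lengths(b))


def plot_summary(dmrs: pd.DataFrame, path=None):
    """Length boxplot by direction plus hyper/hypo bar chart."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 4))
    lengths = dmr_lengths(dmrs)
    direction = dmrs["direction"].to_numpy()
    groups = [lengths[direction == d] for d in ("hyper", "hypo")]
    ax1.boxplot([g if g.size else [0] for g in groups], tick_labels=["hyper", "hypo"])
    ax1.set_ylabel("DMR length (bp)")
    ax2.bar(["hyper", "hypo"], [int((direction == d).sum()) for d in ("hyper", "hypo")],
            color=["crimson", "steelblue"])
    ax2.set_ylabel("DMR count")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
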