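"""Dependence-adjusted region significance: binned autocorrelation,
Stouffer-Liptak combination and FDR correction.

Per-CpG differential-methylation p-values are spatially autocorrelated, so
combining them within a region as if independent is anti-conservative. The
genome is partitioned into ``bin_size``-bp bins; the lag-L autocorrelation of
bin means (p-values are probit-transformed to z = Phi^-1(1-p) before
averaging) yields an ACF that is mapped onto member-CpG pairs through their
distance: sigma_ij = rho[ceil(|pos_i - pos_j| / bin_size)], zero beyond the
largest estimated lag. The combined statistic is

    T = sum_i z_i / sqrt(sum_ij sigma_ij),    p_combined = 1 - Phi(T),

which reduces to the classical Stouffer test for an identity matrix.
Benjamini-Hochberg correction over the combined p-values yields q-values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .regions import DEFAULT_DMC_DIFF, DEFAULT_DMC_QVALUE, is_dmc

_P_CLAMP = 1e-15

DMR_EXTRA_COLUMNS = ["p_combined", "q_value"]


@dataclass(frozen=True)
class AcfEstimate:
    """Autocorrelation of bin means at lags 0..max_lag (lag 0 is 1)."""

    bin_size: int
    rho: np.ndarray
    source: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "rho", np.asarray(self.rho, dtype=float))

    @property
    def lags(self) -> np.ndarray:
        return np.arange(self.rho.size)

    @property
    def max_lag(self) -> int:
        return self.rho.size - 1

    def rho_at(self, lag: int) -> float:
        """rho at an integer lag; 0 beyond the largest estimated lag."""
        return float(self.rho[lag]) if 0 <= lag < self.rho.size else 0.0


def _probit(p: np.ndarray) -> np.ndarray:
    return norm.isf(np.clip(p, _P_CLAMP, 1.0 - _P_CLAMP))


def estimate_acf(cpgs: pd.DataFrame, bin_size: int = 100, max_lag: int = 10,
                 source: str = "pvalue") -> AcfEstimate:
    """Estimate the binned spatial ACF of p-values or methylation differences.

    Bin value = mean over the CpGs falling in each ``bin_size``-bp bin
    (probit scale for p-values); rho[L] is the Pearson correlation over all
    same-chromosome bin pairs exactly L bins apart. Lags with fewer than 3
    pairs or a constant series give rho = 0 with a warning.
    """
    if cpgs.empty:
        raise ValueError("cannot estimate ACF without CpGs")
    if source == "pvalue":
        vals = _probit(cpgs["pvalue"].to_numpy(dtype=float))
    elif source == "meth_diff":
        vals = cpgs["meth_diff"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown ACF source {source!r}")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    binned = (
        pd.DataFrame({
            "chrom": cpgs["chrom"].to_numpy(),
            "bin": (cpgs["pos"].to_numpy() - 1) // bin_size,
            "val": vals,
        })
        .groupby(["chrom", "bin"], sort=True)["val"].mean().reset_index()
    )
    if len(binned) < 2:
        raise ValueError("fewer than 2 non-empty bins")
    rho = np.ones(max_lag + 1)
    for lag in range(1, max_lag + 1):
        shifted = binned.assign(bin=binned["bin"] + lag)
        pairs = binned.merge(shifted, on=["chrom", "bin"], suffixes=("_a", "_b"))
        a, b = pairs["val_a"].to_numpy(), pairs["val_b"].to_numpy()
        if a.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
            warnings.warn(
                f"ACF lag {lag}: undefined correlation ({a.size} pairs); set to 0",
                RuntimeWarning, stacklevel=2,
            )
            rho[lag] = 0.0
        else:
            rho[lag] = float(np.corrcoef(a, b)[0, 1])
    return AcfEstimate(bin_size=bin_size, rho=rho, source=source)


def region_correlation_matrix(positions, acf: AcfEstimate) -> np.ndarray:
    """Map the binned ACF onto member-CpG pairs of one region.

    sigma_ij = rho[ceil(d_ij / bin_size)] with unit diagonal; the matrix is
    repaired to the nearest positive semidefinite matrix (eigenvalue floor at
    0, rescaled back to unit diagonal) when the ACF mapping is indefinite.
    """
    pos = np.asarray(positions, dtype=float)
    k = pos.size
    if k == 0:
        raise ValueError("region has no member CpGs")
    d = np.abs(pos[:, None] - pos[None, :])
    lag = np.ceil(d / acf.bin_size).astype(int)
    sigma = np.where(lag <= acf.max_lag, acf.rho[np.minimum(lag, acf.max_lag)], 0.0)
    np.fill_diagonal(sigma, 1.0)
    eigvals = np.linalg.eigvalsh(sigma)
    if eigvals[0] < -1e-10:
        w, v = np.linalg.eigh(sigma)
        sigma = (v * np.maximum(w, 0.0)) @ v.T
        diag = np.sqrt(np.maximum(np.diag(sigma), 1e-12))
        sigma = sigma / np.outer(diag, diag)
        np.fill_diagonal(sigma, 1.0)
    return sigma


def stouffer_liptak(pvalues, corr: np.ndarray) -> float:
    """Dependence-adjusted Stouffer-Liptak combination of p-values.

    z_i = Phi^-1(1 - p_i) (p clamped to [1e-15, 1 - 1e-15]);
    T = sum(z) / sqrt(sum(corr)); returns 1 - Phi(T).
    """
    p = np.asarray(pvalues, dtype=float)
    corr = np.asarray(corr, dtype=float)
    k = p.size
    if k == 0:
        raise ValueError("no p-values to combine")
    if corr.shape != (k, k):
        raise ValueError(f"correlation matrix shape {corr.shape} does not match {k} p-values")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix is not symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    total = float(corr.sum())
    if total <= 0:
        raise ValueError("degenerate correlation: non-positive matrix sum")
    t = float(_probit(p).sum()) / math.sqrt(total)
    return float(norm.sf(t))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def assign_significance(regions: pd.DataFrame, labelled_cpgs: pd.DataFrame,
                        acf: AcfEstimate, combine: str = "all",
                        dmc_qvalue: float = DEFAULT_DMC_QVALUE,
                        dmc_diff: float = DEFAULT_DMC_DIFF) -> pd.DataFrame:
    """Attach combined p-values and BH q-values to (filtered) regions.

    ``combine='all'`` uses every member CpG p-value; ``combine='dmc-only'``
    restricts to DMCs (falling back to all members for a region without any,
    which cannot occur after the DMC filter).
    """
    if combine not in ("all", "dmc-only"):
        raise ValueError(f"unknown combine mode {combine!r}")
    out = regions.copy()
    if out.empty:
        out["p_combined"] = pd.Series(dtype=float)
        out["q_value"] = pd.Series(dtype=float)
        return out
    members = labelled_cpgs[labelled_cpgs["region_id"].isin(out["region_id"])]
    grouped = dict(tuple(members.groupby("region_id", sort=False)))
    p_combined = np.empty(len(out))
    for i, rid in enumerate(out["region_id"].to_numpy()):
        g = grouped[rid]
        if combine == "dmc-only":
            sel = g[is_dmc(g, dmc_qvalue, dmc_diff)]
            if sel.empty:
                sel = g
        else:
            sel = g
        corr = region_correlation_matrix(sel["pos"].to_numpy(), acf)
        p_combined[i] = stouffer_liptak(sel["pvalue"].to_numpy(), corr)
    out["p_combined"] = p_combined
    out["q_value"] = bh_fdr(p_combined)
    return out
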