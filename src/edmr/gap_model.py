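"""Empirical region-boundary distance from the adjacent-CpG gap distribution.

Enrichment bisulfite protocols (RRBS/ERRBS) concentrate coverage in CpG-rich
fragments, so covered CpGs come in clusters: the log2 distance between
adjacent covered CpGs is bimodal, with a small-gap mode for CpGs inside a
cluster ("regional" CpGs) and a large-gap mode for cluster boundaries. A
1-bp spike (log2 = 0) from non-destranded opposite-strand CpG/GpC pairs is
removed before fitting.

A two-component normal mixture

    F(x) = lam1 * N(mu1, sigma1^2) + lam2 * N(mu2, sigma2^2),   mu1 < mu2,

is fitted by EM to the retained log2 gaps. The boundary cutoff is the point
minimizing the weighted misclassification cost

    C(x) = lam1 * P1(X >= x) + lam2 * P2(X <= x),

i.e. the expected fraction of gaps assigned to the wrong component when
splitting at x. The minimizer x_hat satisfies lam1*f1(x_hat) =
lam2*f2(x_hat) (weighted density crossing); its base-pair form
D = round(2**x_hat) is the segmentation cutoff.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.special import logsumexp
from scipy.stats import norm

from .exceptions import DegenerateMixtureError, InsufficientDataError

_SIGMA_FLOOR = 1e-6
_LAMBDA_FLOOR = 1e-4


@dataclass(frozen=True)
class GapSample:
    """Retained log2 adjacent-CpG distances plus the removed 1-bp spike count."""

    values: np.ndarray
    n_removed_spike: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class MixtureFit:
    """Two-component univariate normal mixture, relabelled so mu1 < mu2."""

    lambda1: float
    lambda2: float
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    loglik: float
    n_iter: int
    converged: bool

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MixtureFit":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class CutoffResult:
    """Optimized log2 separation point and its base-pair form."""

    x_hat: float
    D: int
    cost_at_min: float
    fit: MixtureFit


def compute_gap_sample(cpgs: pd.DataFrame, min_size: int = 500) -> GapSample:
    """Log2 distances between adjacent CpGs, computed within chromosomes.

    Distances of <= 1 bp (the opposite-strand spike, plus same-position
    opposite-strand records) are removed and counted separately; they carry
    no information about region boundaries.
    """
    chunks = []
    n_spike = 0
    for _, sub in cpgs.groupby("chrom", sort=False):
        pos = np.sort(sub["pos"].to_numpy())
        if pos.size < 2:
            continue
        d = np.diff(pos)
        n_spike += int((d <= 1).sum())
        d = d[d > 1]
        if d.size:
            chunks.append(np.log2(d.astype(float)))
    values = np.concatenate(chunks) if chunks else np.empty(0)
    if values.size < max(min_size, 1):
        raise InsufficientDataError(
            f"insufficient gap sample: {values.size} retained log2 distances "
            f"(minimum {min_size}; {n_spike} removed at the 1-bp spike)"
        )
    return GapSample(values, n_spike)


def _as_values(sample) -> np.ndarray:
    return sample.values if isinstance(sample, GapSample) else np.asarray(sample, dtype=float)


def fit_bimodal_em(sample, seed: int = 0, tol: float = 1e-8, max_iter: int = 1000) -> MixtureFit:
    """Fit the two-component normal mixture by EM.

    Initialization splits the sample at its median and takes component
    moments from each half, which is deterministic and avoids label flips;
    ``seed`` is accepted for interface stability but unused by this
    initializer. Convergence is declared when the observed-data log-likelihood
    changes by less than ``tol * (1 + |loglik|)``.

    Raises
    ------
    DegenerateMixtureError
        If the sample is constant or a component collapses
        (sigma < 1e-6 or lambda < 1e-4).
    """
    x = _as_values(sample)
    if x.size < 4:
        raise InsufficientDataError(f"need >= 4 values to fit a mixture, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateMixtureError("constant-valued sample")

    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    fallback = max(float(np.std(x)) / 2.0, _SIGMA_FLOOR * 10)
    mu = np.array([lo.mean(), hi.mean() if hi.size else lo.mean() + fallback])
    sigma = np.array([
        max(float(np.std(lo)), fallback),
        max(float(np.std(hi)) if hi.size else fallback, fallback),
    ])
    lam = np.array([0.5, 0.5])

    loglik = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        logp = np.log(lam)[None, :] + norm.logpdf(x[:, None], mu[None, :], sigma[None, :])
        row_ll = logsumexp(logp, axis=1)
        new_loglik = float(row_ll.sum())
        resp = np.exp(logp - row_ll[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk < _LAMBDA_FLOOR * x.size):
            raise DegenerateMixtureError(
                f"degenerate mixture: mixing proportion below {_LAMBDA_FLOOR}"
            )
        lam = nk / x.size
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sigma = np.sqrt(np.maximum(var, _SIGMA_FLOOR**2))
        if abs(new_loglik - loglik) < tol * (1.0 + abs(new_loglik)):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

    if np.any(sigma < _SIGMA_FLOOR):
        raise DegenerateMixtureError("degenerate mixture: vanishing component variance")
    if np.any(lam < _LAMBDA_FLOOR):
        raise DegenerateMixtureError("degenerate mixture: vanishing mixing proportion")

    order = np.argsort(mu)  # component 1 = regional (small-gap) mode
    lam, mu, sigma = lam[order], mu[order], sigma[order]
    return MixtureFit(
        lambda1=float(lam[0]), lambda2=float(lam[1]),
        mu1=float(mu[0]), mu2=float(mu[1]),
        sigma1=float(sigma[0]), sigma2=float(sigma[1]),
        loglik=float(loglik), n_iter=n_iter, converged=converged,
    )


def cost(x, fit: MixtureFit):
    """Weighted misclassification cost C(x) = lam1*P1(X>=x) + lam2*P2(X<=x).

    Accepts a scalar or array; the value lies in [0, 1], tending to lam1 as
    x -> -inf and lam2 as x -> +inf.
    """
    x = np.asarray(x, dtype=float)
    c = fit.lambda1 * norm.sf(x, fit.mu1, fit.sigma1) + fit.lambda2 * norm.cdf(x, fit.mu2, fit.sigma2)
    return float(c) if c.ndim == 0 else c


def _density_gap(x: float, fit: MixtureFit) -> float:
    """lam2*f2(x) - lam1*f1(x); zero at the weighted-density crossing."""
    return fit.lambda2 * norm.pdf(x, fit.mu2, fit.sigma2) - fit.lambda1 * norm.pdf(
        x, fit.mu1, fit.sigma1
    )


def optimize_cutoff(fit: MixtureFit, sample) -> CutoffResult:
    """Minimize C(x) over the observed log2-gap range.

    Uses bounded 1-D scalar minimization (Brent-type) and then polishes the
    result by root-finding on dC/dx = lam2*f2 - lam1*f1 when the stationary
    point is bracketed, so an interior minimum satisfies the crossing
    condition lam1*f1(x_hat) = lam2*f2(x_hat) to high precision.
    """
    values = _as_values(sample)
    if values.size == 0:
        raise InsufficientDataError("empty gap sample")
    lo, hi = float(values.min()), float(values.max())
    res = minimize_scalar(lambda t: cost(t, fit), bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    x_hat = float(res.x)

    for half_width in (1e-3, 1e-2, 0.1, 0.5):
        a, b = max(lo, x_hat - half_width), min(hi, x_hat + half_width)
        if a < b and _density_gap(a, fit) < 0 < _density_gap(b, fit):
            root = brentq(_density_gap, a, b, args=(fit,), xtol=1e-12)
            if cost(root, fit) <= cost(x_hat, fit) + 1e-12:
                x_hat = float(root)
            break

    span = hi - lo
    if min(x_hat - lo, hi - x_hat) < 1e-3 * span:
        warnings.warn(
            "no interior minimum of the cost function; mixture components may not separate",
            RuntimeWarning,
            stacklevel=2,
        )
    return CutoffResult(
        x_hat=x_hat,
        D=max(2, int(round(2.0**x_hat))),
        cost_at_min=cost(x_hat, fit),
        fit=fit,
    )


def plot_gap_fit(sample: GapSample, fit: MixtureFit, cutoff: CutoffResult | None = None,
                 path=None):
    """Diagnostic figure: gap histogram, fitted components, and cost curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = _as_values(sample)
    grid = np.linspace(x.min(), x.max(), 512)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 7), sharex=True)
    ax1.hist(x, bins=100, density=True, color="0.8", label="log2 gaps")
    ax1.plot(grid, fit.lambda1 * norm.pdf(grid, fit.mu1, fit.sigma1), "r-", label="regional")
    ax1.plot(grid, fit.lambda2 * norm.pdf(grid, fit.mu2, fit.sigma2), "g-", label="boundary")
    ax1.set_ylabel("density")
    ax1.legend(frameon=False)
    ax2.plot(grid, cost(grid, fit), "b-", label="cost C(x)")
    if cutoff is not None:
        for ax in (ax1, ax2):
            ax.axvline(cutoff.x_hat, color="r", ls="--",
                       label=f"x_hat={cutoff.x_hat:.2f} (D={cutoff.D} bp)")
    ax2.set_xlabel("log2 distance between adjacent CpGs")
    ax2.set_ylabel("weighted misclassification cost")
    ax2.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
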