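"""Standard K-class Gaussian mixture EM on intensity data.

The classical intensity model: voxel intensities y_n are i.i.d. draws from
a K-component Gaussian mixture with weights ω_i and per-class parameters
θ_i = (μ_i, σ_i²).  The E-step computes posterior class probabilities
p(i | y_n); the M-step re-estimates (ω, μ, σ²) from posterior-weighted
moments; iteration continues until the relative log-likelihood change
drops below tolerance.  This provides the symmetric baseline segmentation
and the per-mode initialisation consumed by the asymmetric stage.

Fitting operates on the binned histogram (counts as frequency weights),
which is equivalent to fitting the raw voxels up to binning and much
faster on megavoxel volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import Histogram

__all__ = [
    "GaussianParams",
    "MixtureFitResult",
    "gaussian_density",
    "e_step",
    "m_step",
    "fit_em",
]


@dataclass
class GaussianParams:
    """One mixture component: weight ω, mean μ, variance σ²."""

    weight: float
    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValueError("weight must be positive")
        if not self.variance > 0:
            raise ValueError("variance must be positive")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.variance))


@dataclass
class MixtureFitResult:
    """Outcome of an EM fit: parameters, likelihood trace, convergence."""

    params: list[GaussianParams]
    log_likelihood: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def gaussian_density(y: np.ndarray | float, p: GaussianParams) -> np.ndarray | float:
    """Normal density N(y; μ, σ²)."""
    y = np.asarray(y, dtype=float)
    out = np.exp(-((y - p.mean) ** 2) / (2.0 * p.variance)) / np.sqrt(2.0 * np.pi * p.variance)
    return out if out.ndim else float(out)


def _log_densities(y: np.ndarray, params: list[GaussianParams]) -> np.ndarray:
    """log(ω_i p(y|θ_i)) matrix, shape (n, K)."""
    y = y[:, None]
    mu = np.array([p.mean for p in params])[None, :]
    var = np.array([p.variance for p in params])[None, :]
    w = np.array([p.weight for p in params])[None, :]
    return np.log(w) - 0.5 * np.log(2.0 * np.pi * var) - (y - mu) ** 2 / (2.0 * var)


def e_step(y: np.ndarray, params: list[GaussianParams]) -> np.ndarray:
    """Posterior responsibility matrix p(i | y_n), shape (n, K).

    Computed in log-space so rows never contain NaN even when every
    component density underflows at some y.
    """
    w = np.array([p.weight for p in params])
    if not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValueError("mixture weights must be normalized")
    log_wp = _log_densities(np.asarray(y, dtype=float), params)
    log_wp -= log_wp.max(axis=1, keepdims=True)
    post = np.exp(log_wp)
    post /= post.sum(axis=1, keepdims=True)
    return post


def m_step(y: np.ndarray, posteriors: np.ndarray,
           freq: np.ndarray | None = None,
           var_floor: float = 1e-12) -> list[GaussianParams]:
    """Maximisation step: posterior-weighted weights, means and variances.

    ``freq`` supplies per-observation frequency weights (histogram counts);
    omitted, each observation counts once.  A component with vanishing total
    responsibility keeps its mean and is floored to ``var_floor`` variance
    rather than being dropped.
    """
    y = np.asarray(y, dtype=float)
    post = np.asarray(posteriors, dtype=float)
    if not np.allclose(post.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("posterior rows must sum to 1")
    f = np.ones(len(y)) if freq is None else np.asarray(freq, dtype=float)
    wp = post * f[:, None]                       # effective responsibilities
    nk = wp.sum(axis=0)                          # per-class mass
    total = nk.sum()
    out: list[GaussianParams] = []
    for i in range(post.shape[1]):
        if nk[i] <= 0:
            out.append(GaussianParams(weight=1e-12, mean=float(y.mean()), variance=var_floor))
            continue
        mu = float((wp[:, i] * y).sum() / nk[i])
        var = float((wp[:, i] * (y - mu) ** 2).sum() / nk[i])
        out.append(GaussianParams(weight=float(nk[i] / total), mean=mu,
                                  variance=max(var, var_floor)))
    return out


def _init_params(y: np.ndarray, freq: np.ndarray, K: int) -> list[GaussianParams]:
    """Deterministic K-quantile initialisation: split the sorted intensity
    mass into K equal-count groups; per-group mean/variance, equal weights."""
    order = np.argsort(y)
    ys, fs = y[order], freq[order]
    cum = np.cumsum(fs)
    total = cum[-1]
    params = []
    lo = 0.0
    global_var = max(float(np.average((y - np.average(y, weights=freq)) ** 2, weights=freq)), 1e-6)
    for k in range(K):
        hi = total * (k + 1) / K
        sel = (cum > lo) & (cum <= hi) if k else cum <= hi
        if fs[sel].sum() <= 0:
            mu, var = float(y.mean()), global_var
        else:
            mu = float(np.average(ys[sel], weights=fs[sel]))
            var = float(np.average((ys[sel] - mu) ** 2, weights=fs[sel]))
        params.append(GaussianParams(weight=1.0 / K, mean=mu, variance=max(var, global_var * 1e-4)))
        lo = hi
    return params


def _weighted_loglik(y: np.ndarray, freq: np.ndarray, params: list[GaussianParams]) -> float:
    log_wp = _log_densities(y, params)
    m = log_wp.max(axis=1)
    return float((freq * (m + np.log(np.exp(log_wp - m[:, None]).sum(axis=1)))).sum())


def fit_em(data: Histogram | np.ndarray, K: int = 3,
           init: list[GaussianParams] | None = None,
           tol: float = 1e-6, max_iter: int = 500) -> MixtureFitResult:
    """Fit a K-component Gaussian mixture by EM.

    ``data`` is either a :class:`Histogram` (bin centers weighted by counts)
    or a raw 1-D intensity sample.  Convergence: relative log-likelihood
    change < ``tol``.  Hitting ``max_iter`` flags ``converged=False`` rather
    than raising.
    """
    if isinstance(data, Histogram):
        keep = data.counts > 0
        y, freq = data.centers[keep], data.counts[keep].astype(float)
        bw = data.bin_width
    else:
        y = np.asarray(data, dtype=float).ravel()
        freq = np.ones(len(y))
        bw = (y.max() - y.min()) / 256 if len(y) > 1 else 1.0
    if len(np.unique(y)) < K:
        raise ValueError(f"need >= {K} distinct intensity values")
    var_floor = max(bw * bw, 1e-12)
    params = init if init is not None else _init_params(y, freq, K)

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        post = e_step(y, params)
        params = m_step(y, post, freq=freq, var_floor=var_floor)
        ll = _weighted_loglik(y, freq, params)
        trace.append(ll)
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(ll - prev) <= tol * abs(prev):
                converged = True
                break
        if not np.isfinite(tol) or tol == np.inf:
            break
    if not np.isfinite(tol):
        converged = True
    return MixtureFitResult(params=params, log_likelihood=trace, n_iter=it, converged=converged)
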