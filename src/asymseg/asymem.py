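"""Asymmetric-Gaussian modified EM: the core histogram-fitting stage.

Brain tissue intensity distributions on T1 MR are skewed — CSF in
particular spreads across the low end of the histogram — so a symmetric
Gaussian per class misfits one flank.  The model here gives each class an
asymmetric Gaussian density with distinct standard deviations on the two
sides of the mode:

    A(z; μ, σ², r) = sqrt(2/π) / (σ (1 + r)) *
        { exp(-(z-μ)² / (2σ²))        if z > μ,
          exp(-(z-μ)² / (2 r² σ²))    otherwise }

σ is the first-side (right, z > μ) standard deviation and the second-side
(left) SD is r·σ.  r = 1 recovers the symmetric Gaussian; the normaliser
makes the two-branch density integrate to 1 for any r > 0.

The fit proceeds per histogram mode:

1. split the smoothed histogram at its interior local minima (gradient
   sign change with positive concavity) into three modes — CSF, GM, WM in
   order of increasing intensity;
2. per mode, fix μ (density peak) and σ_first (right-flank RMS deviation);
3. search r from 1 in multiplicative 10% steps, scoring each candidate by
   the mean absolute count difference between the modelled and observed
   mode histogram, keeping the r of minimum error (stopping on an RMS-
   derived error threshold, two consecutive error increases, or the search
   bounds).

The fitted three-class mixture yields per-voxel membership probabilities,
an argmax (optionally region-grown) initial labeling, and the overlap
mask of low-confidence voxels handed to the texture/SVM refinement stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import Histogram, LabelMap, Volume3D

__all__ = [
    "AsymGaussianParams",
    "SplitResult",
    "RSearchTrace",
    "split_histogram",
    "asymmetric_density",
    "histogram_error",
    "fit_r",
    "fit_asymmetric_mixture",
    "membership_probability",
    "initial_labeling",
    "detect_overlap_voxels",
]

# Search and thresholding defaults (all overridable per call).
R_STEP = 0.10            # multiplicative step of the r search ("10 percent")
R_BOUNDS = (0.2, 5.0)    # admissible r range
RMS_FACTOR = 0.05        # error threshold = RMS_FACTOR * RMS of mode counts
SMOOTH_WINDOW = 5        # moving-average window (bins) before derivative analysis
OVERLAP_TAU = 0.9        # max-posterior threshold below which a voxel is "overlap"
SEED_THRESHOLD = 0.95    # region growing: seed confidence
ADMIT_THRESHOLD = 0.5    # region growing: neighbor admission confidence


@dataclass
class AsymGaussianParams:
    """Asymmetric Gaussian class parameters (ω, μ, σ_first, r).

    ``sigma_first`` is the right-side SD (z > μ); the left-side SD is
    ``ratio * sigma_first``.  ``ratio == 1`` is the symmetric case.
    """

    weight: float
    mean: float
    sigma_first: float
    ratio: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma_first > 0:
            raise ValueError("sigma_first must be positive")
        if not self.ratio > 0:
            raise ValueError("ratio r must be positive")
        if not self.weight > 0:
            raise ValueError("weight must be positive")

    @property
    def sigma_second(self) -> float:
        """Left-side SD: σ_second = r · σ_first."""
        return self.ratio * self.sigma_first


@dataclass
class SplitResult:
    """Histogram partition into three intensity modes (CSF < GM < WM)."""

    cut_points: tuple[float, float]            # intensity values of the two minima
    cut_bins: tuple[int, int]                  # bin indices of the cuts
    mode_ranges: list[tuple[float, float]]     # three [lo, hi) intensity intervals
    mode_bin_ranges: list[tuple[int, int]]     # three [lo, hi) bin-index intervals


@dataclass
class RSearchTrace:
    """Record of the error-driven search over the asymmetry ratio r."""

    evaluations: list[tuple[float, float]] = field(default_factory=list)  # (r, error)
    chosen_r: float = 1.0
    stop_reason: str = ""  # "threshold" | "error-increase" | "bound"

    def error_at(self, r: float) -> float:
        for rv, e in self.evaluations:
            if np.isclose(rv, r):
                return e
        raise KeyError(f"r={r} not evaluated")


# ---------------------------------------------------------------------------
# Histogram splitting
# ---------------------------------------------------------------------------

def _smooth(counts: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge-shrinking window."""
    if window <= 1:
        return counts.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(counts.astype(float), pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def split_histogram(hist: Histogram, smoothing: int = SMOOTH_WINDOW) -> SplitResult:
    """Partition a three-mode histogram at its two interior minima.

    The cut points are bins where the first finite difference of the
    smoothed counts changes sign from negative to positive and the second
    difference is positive (local minima with upward concavity).  When more
    than two candidate minima exist, the two separating the three largest
    modes (by enclosed count mass) are kept.

    Raises ``ValueError`` when fewer than three modes are present.
    """
    s = _smooth(hist.counts, smoothing)
    d1 = np.diff(s)
    # Local minima with plateau handling: a bin is a minimum when the last
    # nonzero first difference before it is negative (descending into it)
    # and the first nonzero difference at/after it is positive (ascending
    # out) — the sign change of the gradient with positive concavity.
    # Flat runs (e.g. zero-count gaps) collapse to their central bin.
    sign = np.sign(d1)
    prev_sign = np.zeros(len(s))
    last = 0.0
    for i in range(1, len(s)):
        if sign[i - 1] != 0:
            last = sign[i - 1]
        prev_sign[i] = last
    next_sign = np.zeros(len(s))
    nxt = 0.0
    for i in range(len(s) - 2, -1, -1):
        if sign[i] != 0:
            nxt = sign[i]
        next_sign[i] = nxt
    is_min = (prev_sign < 0) & (next_sign > 0)
    minima: list[int] = []
    i = 0
    while i < len(s):
        if is_min[i]:
            j = i
            while j + 1 < len(s) and is_min[j + 1]:
                j += 1
            minima.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    if len(minima) < 2:
        raise ValueError(
            "insufficient modes: fewer than two interior histogram minima; "
            "increase smoothing or check the class count")

    if len(minima) > 2:
        # more minima than true mode boundaries (noise wiggles): keep the
        # minima that separate the three most prominent peaks
        from scipy.signal import find_peaks
        peaks, props = find_peaks(s, prominence=0.0)
        if len(peaks) < 3:
            raise ValueError("insufficient modes: fewer than three histogram peaks")
        top = np.sort(peaks[np.argsort(props["prominences"])[-3:]])
        cuts = []
        for a, b in zip(top[:-1], top[1:]):
            between = [mn for mn in minima if a < mn < b]
            if not between:
                between = [a + int(np.argmin(s[a:b + 1]))]
            cuts.append(min(between, key=lambda mn: s[mn]))
        cut1, cut2 = cuts
    else:
        cut1, cut2 = minima

    edges = hist.bin_edges
    n = hist.n_bins
    return SplitResult(
        cut_points=(float(edges[cut1]), float(edges[cut2])),
        cut_bins=(cut1, cut2),
        mode_ranges=[(float(edges[0]), float(edges[cut1])),
                     (float(edges[cut1]), float(edges[cut2])),
                     (float(edges[cut2]), float(edges[n]))],
        mode_bin_ranges=[(0, cut1), (cut1, cut2), (cut2, n)],
    )


# ---------------------------------------------------------------------------
# Asymmetric density and the fit error
# ---------------------------------------------------------------------------

def asymmetric_density(z: np.ndarray | float, p: AsymGaussianParams) -> np.ndarray | float:
    """Asymmetric Gaussian density A(z; μ, σ², r).

    Continuous at z = μ, maximal there, and integrates to 1: the right
    half-integral is σ√(π/2) and the left is rσ√(π/2), so the normaliser
    √(2/π)/(σ(1+r)) makes the total unity for any r > 0.
    """
    z = np.asarray(z, dtype=float)
    mu, s, r = p.mean, p.sigma_first, p.ratio
    norm = np.sqrt(2.0 / np.pi) / (s * (1.0 + r))
    dz = z - mu
    right = np.exp(-(dz ** 2) / (2.0 * s * s))
    left = np.exp(-(dz ** 2) / (2.0 * r * r * s * s))
    out = norm * np.where(dz > 0, right, left)
    return out if out.ndim else float(out)


def histogram_error(f: np.ndarray, g: np.ndarray) -> float:
    """Mean absolute per-bin count difference (1/N) Σ |f_i − g_i|."""
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != g.shape:
        raise ValueError(f"count vectors differ in length: {f.shape} vs {g.shape}")
    return float(np.abs(f - g).mean())


def _model_counts(hist: Histogram, p: AsymGaussianParams, total: float) -> np.ndarray:
    """Predicted per-bin counts: total × density at bin midpoint × bin width."""
    return total * np.asarray(asymmetric_density(hist.centers, p)) * hist.bin_width


def fit_r(mode_hist: Histogram, mu: float, sigma_first: float,
          step: float = R_STEP, threshold: float | None = None,
          r_bounds: tuple[float, float] = R_BOUNDS) -> tuple[AsymGaussianParams, RSearchTrace]:
    """Error-driven search for the asymmetry ratio r of one histogram mode.

    μ and σ_first stay fixed; r starts at 1 and moves in multiplicative
    steps of (1+step).  If the first upward step increases the error the
    search reverses to factors of 1/(1+step).  Stopping: error ≤ threshold
    (default ``RMS_FACTOR`` × RMS of the mode's counts), two consecutive
    error increases, or a bound of ``r_bounds``.  The returned parameters
    carry the r of minimum observed error, so the fit is never worse than
    the symmetric start.
    """
    counts = np.asarray(mode_hist.counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty mode histogram")
    if threshold is None:
        threshold = RMS_FACTOR * float(np.sqrt(np.mean(counts ** 2)))

    def err(r: float) -> float:
        p = AsymGaussianParams(weight=1.0, mean=mu, sigma_first=sigma_first, ratio=r)
        return histogram_error(counts, _model_counts(mode_hist, p, total))

    trace = RSearchTrace()
    r = 1.0
    e = err(r)
    trace.evaluations.append((r, e))
    stop = ""
    if e <= threshold:
        stop = "threshold"
    else:
        # probe upward once to pick the search direction
        factor = 1.0 + step
        r_up = r * factor
        e_up = err(r_up)
        trace.evaluations.append((r_up, e_up))
        if e_up <= threshold:
            stop = "threshold"
        else:
            if e_up >= e:
                factor = 1.0 / (1.0 + step)  # error grew: decrease r instead
            cur_r = r * factor
            cur_e = err(cur_r) if factor < 1 else e_up
            if factor < 1:
                trace.evaluations.append((cur_r, cur_e))
            prev_e = e
            increases = 1 if cur_e >= prev_e else 0
            while True:
                if cur_e <= threshold:
                    stop = "threshold"
                    break
                if increases >= 2:
                    stop = "error-increase"
                    break
                nxt_r = cur_r * factor
                if not (r_bounds[0] <= nxt_r <= r_bounds[1]):
                    stop = "bound"
                    break
                nxt_e = err(nxt_r)
                trace.evaluations.append((nxt_r, nxt_e))
                increases = increases + 1 if nxt_e >= cur_e else 0
                cur_r, cur_e = nxt_r, nxt_e

    rs, es = zip(*trace.evaluations)
    best = int(np.argmin(es))
    trace.chosen_r = float(rs[best])
    trace.stop_reason = stop or "threshold"
    params = AsymGaussianParams(weight=1.0, mean=mu, sigma_first=sigma_first,
                                ratio=trace.chosen_r)
    return params, trace


# ---------------------------------------------------------------------------
# Per-mode initialisation and the three-class fit
# ---------------------------------------------------------------------------

def _sigma_first_at(mode_hist: Histogram, mu: float) -> float:
    """Right-flank scale: conditional on z > μ the right branch is
    half-normal with scale σ_first, whose second moment about μ is
    σ_first² exactly."""
    centers = mode_hist.centers
    right = centers > mu
    w = mode_hist.counts[right].astype(float)
    if w.sum() > 0:
        sigma = float(np.sqrt(np.sum(w * (centers[right] - mu) ** 2) / w.sum()))
    else:
        sigma = 0.0
    return max(sigma, mode_hist.bin_width)  # floor: one bin width


def _mode_init(mode_hist: Histogram, smoothing: int = SMOOTH_WINDOW) -> tuple[float, float]:
    """Initial (μ, σ_first) for one mode.

    μ starts at the peak of the smoothed mode counts — the asymmetric
    density is maximal exactly at its mean parameter, so the peak locates
    μ without the skew-induced offset a symmetric moment fit would carry.
    (Smoothing itself drags the discrete peak slightly toward the heavy
    flank; :func:`fit_asymmetric_mixture` refines μ on a sub-bin grid by
    the same fit-error criterion used for r.)
    """
    s = _smooth(mode_hist.counts, smoothing)
    peak = int(np.argmax(s))
    mu = float(mode_hist.centers[peak])
    return mu, _sigma_first_at(mode_hist, mu)


def fit_asymmetric_mixture(hist: Histogram, smoothing: int = SMOOTH_WINDOW,
                           step: float = R_STEP,
                           threshold: float | None = None,
                           r_bounds: tuple[float, float] = R_BOUNDS,
                           ) -> tuple[list[AsymGaussianParams], SplitResult, list[RSearchTrace]]:
    """Fit the three-class asymmetric mixture to a foreground histogram.

    Splits the histogram into three modes, then per mode fixes (μ,
    σ_first) and searches r; class weights are the mode count fractions.
    Classes are returned in increasing-intensity order (CSF, GM, WM).
    """
    split = split_histogram(hist, smoothing=smoothing)
    total = float(hist.counts.sum())
    bw = hist.bin_width
    params: list[AsymGaussianParams] = []
    traces: list[RSearchTrace] = []
    for k, (lo, hi) in enumerate(split.mode_bin_ranges):
        mode = hist.slice(lo, hi)
        try:
            mu0, _ = _mode_init(mode, smoothing=smoothing)
            # refine μ on a half-bin grid around the smoothed peak, scoring
            # each candidate by the same fit error that drives the r search
            # (discrete peaks sit up to ~a bin off the true density maximum)
            best: tuple[AsymGaussianParams, RSearchTrace] | None = None
            best_err = np.inf
            for mu in mu0 + bw * np.arange(-2.0, 2.01, 0.5):
                sigma = _sigma_first_at(mode, mu)
                p, tr = fit_r(mode, mu, sigma, step=step, threshold=threshold,
                              r_bounds=r_bounds)
                err = min(e for _, e in tr.evaluations)
                if err < best_err:
                    best, best_err = (p, tr), err
            assert best is not None
            p, tr = best
        except ValueError as exc:
            raise ValueError(f"mode {k}: {exc}") from exc
        p.weight = float(mode.counts.sum() / total)
        params.append(p)
        traces.append(tr)
    return params, split, traces


# ---------------------------------------------------------------------------
# Membership probabilities, labeling, overlap detection
# ---------------------------------------------------------------------------

def _log_asym_density(z: np.ndarray, p: AsymGaussianParams) -> np.ndarray:
    mu, s, r = p.mean, p.sigma_first, p.ratio
    dz = z - mu
    log_norm = 0.5 * np.log(2.0 / np.pi) - np.log(s * (1.0 + r))
    expo = np.where(dz > 0, -(dz ** 2) / (2 * s * s), -(dz ** 2) / (2 * r * r * s * s))
    return log_norm + expo


def membership_probability(vol: Volume3D, params: list[AsymGaussianParams],
                           foreground: np.ndarray | None = None) -> np.ndarray:
    """Per-voxel posterior over the K classes, shape (*vol.shape, K).

    Bayes posterior with the asymmetric densities in place of the
    Gaussian; computed in log-space.  Background voxels (foreground mask
    false) get an all-zero row — the posterior is undefined there.
    """
    z = vol.data.astype(float)
    if foreground is None:
        foreground = z != 0
    zf = z[foreground]
    logp = np.stack([np.log(p.weight) + _log_asym_density(zf, p) for p in params], axis=-1)
    logp -= logp.max(axis=-1, keepdims=True)
    post = np.exp(logp)
    post /= post.sum(axis=-1, keepdims=True)
    out = np.zeros(z.shape + (len(params),), dtype=float)
    out[foreground] = post
    return out


_NEIGHBORS_26 = np.array([(dx, dy, dz)
                          for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                          if (dx, dy, dz) != (0, 0, 0)], dtype=int)


def initial_labeling(posteriors: np.ndarray, region_grow: bool = False,
                     seed_threshold: float = SEED_THRESHOLD,
                     admit_threshold: float = ADMIT_THRESHOLD) -> LabelMap:
    """Argmax tissue labels from the membership posteriors.

    Ties go to the lowest class index (stable argmax).  With
    ``region_grow`` enabled, labels propagate breadth-first from
    high-confidence seeds (max posterior ≥ ``seed_threshold``) through
    26-connected foreground neighbors: a neighbor confident in its own
    argmax class (max posterior ≥ ``admit_threshold``) keeps that class,
    while a low-confidence neighbor inherits the label of the voxel that
    reached it.  Each voxel is visited once; unreached foreground voxels
    fall back to their argmax label.
    """
    post = np.asarray(posteriors, dtype=float)
    fg = post.sum(axis=-1) > 0
    arg = np.argmax(post, axis=-1) + 1        # np.argmax takes the first max: low index wins
    labels = np.where(fg, arg, 0).astype(np.int16)

    if region_grow and fg.any():
        maxpost = post.max(axis=-1)
        grown = np.zeros(labels.shape, dtype=np.int16)
        visited = np.zeros(labels.shape, dtype=bool)
        seeds = np.argwhere(fg & (maxpost >= seed_threshold))
        from collections import deque
        queue: deque[tuple[int, int, int]] = deque()
        for idx in seeds:
            t = tuple(idx)
            grown[t] = labels[t]
            visited[t] = True
            queue.append(t)
        shape = labels.shape
        while queue:
            v = queue.popleft()
            for off in _NEIGHBORS_26:
                n = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if not (0 <= n[0] < shape[0] and 0 <= n[1] < shape[1] and 0 <= n[2] < shape[2]):
                    continue
                if visited[n] or not fg[n]:
                    continue
                visited[n] = True
                grown[n] = labels[n] if maxpost[n] >= admit_threshold else grown[v]
                queue.append(n)
        unreached = fg & ~visited
        grown[unreached] = labels[unreached]
        labels = grown

    return LabelMap(labels=labels)


def detect_overlap_voxels(posteriors: np.ndarray, tau: float = OVERLAP_TAU
                          ) -> tuple[np.ndarray, dict[tuple[int, int], int]]:
    """Flag ambiguous foreground voxels: max posterior < tau.

    Returns the boolean overlap mask and a count of flagged voxels per
    adjacent class pair (top-two posterior classes, low index first).
    """
    post = np.asarray(posteriors, dtype=float)
    fg = post.sum(axis=-1) > 0
    maxpost = post.max(axis=-1)
    mask = fg & (maxpost < tau)
    pair_counts: dict[tuple[int, int], int] = {}
    if mask.any():
        flagged = post[mask]
        top2 = np.argsort(flagged, axis=-1)[:, -2:]
        for a, b in top2:
            key = tuple(sorted((int(a) + 1, int(b) + 1)))
            pair_counts[key] = pair_counts.get(key, 0) + 1
    return mask, pair_counts
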