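"""Ground-truthed synthetic brain phantoms.

Generates three-tissue (CSF/GM/WM) volumes with the statistical structure
the segmentation method assumes — per-tissue *asymmetric* Gaussian
intensity distributions, optional Rician noise at a selectable level, and
an optional smooth multiplicative bias field — on a simple nested-
ellipsoid geometry (CSF outer shell, GM middle shell, WM core on a zero
background).  The geometry gives genuine 3-D tissue borders for the
overlap-detection and SVM stages without anatomical realism.

Default intensity parameters emulate skull-stripped T1 contrast on a
0–255 scale: CSF dark with a heavy low-side tail (its intensity spreads
across the bottom of the histogram), GM mid, WM bright.  Noise levels are
fractions of the WM mean, mirroring the percent-noise convention of
simulated-brain databases (0 → 0.09 covers the usual 0%–9% range); bias
amplitude is the fractional peak deviation of the multiplicative field
(0.2 and 0.4 mirror the common 20%/40% inhomogeneity settings).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .asymem import AsymGaussianParams
from .volume_io import LabelMap, Volume3D

__all__ = ["PhantomSpec", "generate_phantom", "sample_asymmetric_mixture"]


def _default_class_params() -> dict[int, AsymGaussianParams]:
    # weight fields here are only used by sample_asymmetric_mixture; the
    # phantom's class proportions come from the geometry.
    return {
        1: AsymGaussianParams(weight=0.2, mean=40.0, sigma_first=6.0, ratio=2.0),   # CSF
        2: AsymGaussianParams(weight=0.5, mean=105.0, sigma_first=6.0, ratio=1.3),  # GM
        3: AsymGaussianParams(weight=0.3, mean=170.0, sigma_first=6.0, ratio=1.2),  # WM
    }


def _default_geometry(shape: tuple[int, int, int]) -> dict[int, tuple[float, ...]]:
    """Nested ellipsoid semi-axes per tissue, scaled to the grid."""
    f = min(shape) / 64.0
    return {
        1: (28 * f, 26 * f, 24 * f),  # CSF: outermost shell
        2: (22 * f, 20 * f, 19 * f),  # GM: middle shell
        3: (13 * f, 12 * f, 11 * f),  # WM: core
    }


@dataclass
class PhantomSpec:
    """Parameters of one synthetic phantom realisation.

    noise_sigma — Rician noise scale as a fraction of the WM mean
    (0.05 = "5% noise").  bias_amplitude — fractional peak deviation of
    the smooth multiplicative bias field, in [0, 0.5].
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    class_params: dict[int, AsymGaussianParams] = field(default_factory=_default_class_params)
    noise_sigma: float = 0.0
    bias_amplitude: float = 0.0
    geometry: dict[int, tuple[float, ...]] | None = None
    center: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.bias_amplitude <= 0.5:
            raise ValueError("bias_amplitude must be in [0, 0.5]")
        if self.geometry is None:
            self.geometry = _default_geometry(self.shape)
        if self.center is None:
            self.center = tuple((s - 1) / 2.0 for s in self.shape)  # type: ignore[assignment]
        axes = [self.geometry[k] for k in (1, 2, 3)]
        for outer, inner in zip(axes, axes[1:]):
            if not all(i < o for i, o in zip(inner, outer)):
                raise ValueError("geometry error: tissue shells must be strictly nested "
                                 "(CSF ⊃ GM ⊃ WM)")
        if not all(a < s / 2 for a, s in zip(axes[0], self.shape)):
            raise ValueError("geometry error: outer shell must fit inside the grid")


def _ellipsoid_mask(shape: tuple[int, int, int], center: tuple[float, ...],
                    semi_axes: tuple[float, ...]) -> np.ndarray:
    grids = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return q <= 1.0


def _sample_one_class(p: AsymGaussianParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n values from one asymmetric Gaussian.

    The density's right lobe holds fraction 1/(1+r) of the mass and is
    half-normal with scale σ; the left lobe holds r/(1+r) with scale rσ.
    """
    side_right = rng.random(n) < 1.0 / (1.0 + p.ratio)
    mags = np.abs(rng.normal(0.0, 1.0, n))
    out = np.where(side_right,
                   p.mean + mags * p.sigma_first,
                   p.mean - mags * p.ratio * p.sigma_first)
    return out


def sample_asymmetric_mixture(params: list[AsymGaussianParams], n: int,
                              seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw n intensities from a mixture of asymmetric Gaussians.

    Component weights must sum to 1; each draw picks a component by its
    weight and then samples that component's two-sided density.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    w = np.array([p.weight for p in params], dtype=float)
    if not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValueError("mixture weights must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comp = rng.choice(len(params), size=n, p=w)
    out = np.empty(n, dtype=float)
    for i, p in enumerate(params):
        idx = np.nonzero(comp == i)[0]
        if idx.size:
            out[idx] = _sample_one_class(p, idx.size, rng)
    return out


def _bias_field(shape: tuple[int, int, int], amplitude: float,
                rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field: degree-2 polynomial in x, y, z with
    random coefficients, scaled to peak fractional deviation ``amplitude``
    and renormalised to mean 1."""
    if amplitude == 0:
        return np.ones(shape)
    coords = [np.linspace(-1, 1, s) for s in shape]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    c = rng.normal(0.0, 1.0, 10)
    q = (c[0] + c[1] * x + c[2] * y + c[3] * z
         + c[4] * x * y + c[5] * x * z + c[6] * y * z
         + c[7] * x * x + c[8] * y * y + c[9] * z * z)
    q -= q.mean()
    peak = np.abs(q).max()
    field = 1.0 + amplitude * q / (peak if peak > 0 else 1.0)
    return field / field.mean()


def generate_phantom(spec: PhantomSpec) -> tuple[Volume3D, LabelMap]:
    """Generate one phantom volume with its exact ground-truth label map.

    Per-voxel intensity is drawn from that voxel's class density, then
    multiplied by the bias field, then Rician-corrupted
    (sqrt((signal+g1)² + g2²) with independent zero-mean Gaussians g1, g2
    of scale noise_sigma × WM mean).  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.zeros(spec.shape, dtype=np.int16)
    # paint outermost first so inner shells overwrite
    for code in (1, 2, 3):
        mask = _ellipsoid_mask(spec.shape, spec.center, spec.geometry[code])  # type: ignore[index]
        labels[mask] = code

    data = np.zeros(spec.shape, dtype=float)
    for code in (1, 2, 3):
        m = labels == code
        n = int(m.sum())
        if n:
            # foreground intensities clipped positive so they stay distinct
            # from the exact-zero background
            data[m] = np.maximum(_sample_one_class(spec.class_params[code], n, rng), 1e-3)

    data *= _bias_field(spec.shape, spec.bias_amplitude, rng)

    if spec.noise_sigma > 0:
        sigma = spec.noise_sigma * spec.class_params[3].mean
        fg = labels != 0
        g1 = rng.normal(0.0, sigma, spec.shape)
        g2 = rng.normal(0.0, sigma, spec.shape)
        noisy = np.sqrt((data + g1) ** 2 + g2 ** 2)
        data = np.where(fg, noisy, data)  # background stays exactly zero

    vol = Volume3D(data=data)
    return vol, LabelMap(labels=labels)
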