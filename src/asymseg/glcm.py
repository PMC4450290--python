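"""3-D gray-level co-occurrence matrices and Haralick texture features.

A GLCM counts how often a pair of quantized gray levels (i, j) occurs at
voxel positions separated by d·offset for a displacement offset and
integer distance d.  In 3-D, 13 unique directions cover the 26-voxel
neighborhood (antipodal offsets are redundant under symmetric
accumulation).  Features are computed inside a local window (default
21×21×21) centered on each voxel of interest (VOI): for every distance
d = 1..5, thirteen GLCMs (one per direction) each yield the canonical 13
Haralick descriptors, aggregated as mean and population standard
deviation across the 13 directions — 26 values per distance, 130 per VOI.

Gray levels are quantized to N_g = 32 equal-width levels by default;
background (level 0) voxels never participate in pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import LabelMap, Volume3D

__all__ = [
    "HARALICK_NAMES",
    "DirectionSet",
    "GLCM",
    "FeatureVector",
    "enumerate_directions_3d",
    "quantize",
    "compute_glcm",
    "haralick_features",
    "feature_vector_for_voi",
    "feature_names",
    "extract_target_area",
]

N_LEVELS_DEFAULT = 32
WINDOW_DEFAULT = 21
DISTANCES_DEFAULT = (1, 2, 3, 4, 5)

#: Canonical Haralick-13 feature names, in order.
HARALICK_NAMES = (
    "asm",                 # angular second moment
    "contrast",
    "correlation",
    "variance",            # sum of squares
    "idm",                 # inverse difference moment
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",                # information measure of correlation 1
    "imc2",                # information measure of correlation 2
)


@dataclass(frozen=True)
class DirectionSet:
    """The 13 canonical 3-D displacement directions."""

    offsets: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if len(self.offsets) != 13:
            raise ValueError("a 3-D direction set has exactly 13 offsets")

    def __iter__(self):
        return iter(self.offsets)

    def __len__(self) -> int:
        return len(self.offsets)


def enumerate_directions_3d() -> DirectionSet:
    """All offsets in {-1,0,1}³ \\ {0} whose first nonzero component is
    positive — one representative per antipodal pair, 26/2 = 13 in
    lexicographic order."""
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                v = (dx, dy, dz)
                if v == (0, 0, 0):
                    continue
                first = next(c for c in v if c != 0)
                if first > 0:
                    offs.append(v)
    return DirectionSet(offsets=tuple(sorted(offs)))


@dataclass
class GLCM:
    """Co-occurrence matrix for one (distance, direction) pair.

    ``counts[i-1, j-1]`` is the count (or probability when normalized) of
    level pair (i, j), i, j ∈ 1..n_levels.
    """

    counts: np.ndarray
    n_levels: int
    distance: int
    offset: tuple[int, int, int]
    normalized: bool = False

    def count(self, i: int, j: int) -> float:
        """Entry for gray-level pair (i, j), 1-based levels."""
        return float(self.counts[i - 1, j - 1])

    def normalize(self) -> "GLCM":
        total = self.counts.sum()
        probs = self.counts / total if total > 0 else self.counts.astype(float)
        return GLCM(counts=probs, n_levels=self.n_levels, distance=self.distance,
                    offset=self.offset, normalized=True)


@dataclass
class FeatureVector:
    """130-component texture descriptor for one VOI.

    Layout: distance-major — for d = distances[0..4], for feature f =
    Haralick 1..13, (mean, std) over the 13 directions.
    """

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def feature_names(distances: tuple[int, ...] = DISTANCES_DEFAULT) -> tuple[str, ...]:
    """Ordered names of the full feature layout (130 for 5 distances)."""
    names = []
    for d in distances:
        for f in HARALICK_NAMES:
            names.append(f"d{d}_{f}_mean")
            names.append(f"d{d}_{f}_std")
    return tuple(names)


# ---------------------------------------------------------------------------
# Quantization
# ---------------------------------------------------------------------------

def quantize(vol: Volume3D | np.ndarray, n_levels: int = N_LEVELS_DEFAULT,
             mask: np.ndarray | None = None) -> np.ndarray:
    """Map foreground intensities to levels {1..n_levels} by equal-width
    binning over the masked intensity range; background becomes the
    reserved level 0, never counted in pairs."""
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    data = vol.data if isinstance(vol, Volume3D) else np.asarray(vol)
    if mask is None:
        mask = data != 0
    vals = data[mask]
    if vals.size == 0:
        raise ValueError("empty mask: nothing to quantize")
    lo, hi = float(vals.min()), float(vals.max())
    q = np.zeros(data.shape, dtype=np.int32)
    if hi == lo:
        q[mask] = 1
        return q
    scaled = (data[mask] - lo) / (hi - lo) * n_levels
    q[mask] = np.clip(np.floor(scaled).astype(np.int32) + 1, 1, n_levels)
    return q


# ---------------------------------------------------------------------------
# GLCM accumulation
# ---------------------------------------------------------------------------

def _window_slices(window: tuple[tuple[int, int], ...] | None,
                   shape: tuple[int, ...]) -> tuple[slice, ...]:
    if window is None:
        return tuple(slice(0, s) for s in shape)
    return tuple(slice(max(lo, 0), min(hi, s)) for (lo, hi), s in zip(window, shape))


def _pair_counts(W: np.ndarray, disp: tuple[int, int, int], n_levels: int) -> np.ndarray:
    """Vectorized pair counting inside window array W for displacement disp."""
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, dd in enumerate(disp):
        if dd > 0:
            src[ax] = slice(0, W.shape[ax] - dd)
            dst[ax] = slice(dd, W.shape[ax])
        elif dd < 0:
            src[ax] = slice(-dd, W.shape[ax])
            dst[ax] = slice(0, W.shape[ax] + dd)
        if W.shape[ax] <= abs(dd):
            return np.zeros(n_levels * n_levels, dtype=np.int64)
    a = W[tuple(src)].ravel()
    b = W[tuple(dst)].ravel()
    valid = (a > 0) & (b > 0)
    if not valid.any():
        return np.zeros(n_levels * n_levels, dtype=np.int64)
    idx = (a[valid].astype(np.int64) - 1) * n_levels + (b[valid].astype(np.int64) - 1)
    return np.bincount(idx, minlength=n_levels * n_levels)


def compute_glcm(Q: np.ndarray, offset: tuple[int, int, int], d: int = 1,
                 window: tuple[tuple[int, int], ...] | None = None,
                 n_levels: int | None = None, symmetric: bool = True) -> GLCM:
    """Co-occurrence counts of voxel pairs (v, v + d·offset) within a window.

    Pairs must lie fully inside the (clipped) window and involve no
    background (level-0) voxel.  Symmetric accumulation adds the transpose,
    the standard practice that makes antipodal directions redundant.  A
    window smaller than the displacement yields an all-zero matrix.
    """
    if d < 1:
        raise ValueError("distance d must be >= 1")
    Q = np.asarray(Q)
    if n_levels is None:
        n_levels = int(Q.max())
        if n_levels < 1:
            raise ValueError("quantized volume has no foreground levels")
    W = Q[_window_slices(window, Q.shape)]
    disp = tuple(int(d * o) for o in offset)
    flat = _pair_counts(W, disp, n_levels)  # type: ignore[arg-type]
    counts = flat.reshape(n_levels, n_levels)
    if symmetric:
        counts = counts + counts.T
    return GLCM(counts=counts, n_levels=n_levels, distance=d,
                offset=tuple(offset), normalized=False)


# ---------------------------------------------------------------------------
# Haralick features
# ---------------------------------------------------------------------------

_IDX_CACHE: dict[int, dict[str, np.ndarray]] = {}


def _index_grids(n: int) -> dict[str, np.ndarray]:
    if n not in _IDX_CACHE:
        i = np.arange(1, n + 1, dtype=float)
        I, J = np.meshgrid(i, i, indexing="ij")
        _IDX_CACHE[n] = {
            "I": I, "J": J,
            "sum_idx": (I + J).astype(int),      # 2..2n
            "diff_idx": np.abs(I - J).astype(int),  # 0..n-1
            "idm_w": 1.0 / (1.0 + (I - J) ** 2),
        }
    return _IDX_CACHE[n]


def _xlog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0·log0 := 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def haralick_features(glcm: GLCM) -> np.ndarray:
    """The canonical 13 Haralick descriptors of a normalized GLCM.

    Order follows :data:`HARALICK_NAMES`.  Logarithms are base 2 with
    0·log 0 = 0.  Degenerate guards: correlation is 0 when either marginal
    is constant; information correlation 1 is 0 when HX = HY = 0; the sum-
    variance center is the sum average.  An all-zero matrix (no pairs)
    yields all-zero features.
    """
    if not glcm.normalized:
        raise ValueError("haralick_features requires a normalized GLCM")
    p = np.asarray(glcm.counts, dtype=float)
    if p.sum() <= 0:
        return np.zeros(13)
    n = glcm.n_levels
    g = _index_grids(n)
    I, J = g["I"], g["J"]

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    i = np.arange(1, n + 1, dtype=float)
    mu_x = float(px @ i)
    mu_y = float(py @ i)
    sd_x = float(np.sqrt(px @ (i - mu_x) ** 2))
    sd_y = float(np.sqrt(py @ (i - mu_y) ** 2))

    p_sum = np.bincount(g["sum_idx"].ravel(), weights=p.ravel(), minlength=2 * n + 1)[2:]
    p_diff = np.bincount(g["diff_idx"].ravel(), weights=p.ravel(), minlength=n)

    ks = np.arange(2, 2 * n + 1, dtype=float)
    kd = np.arange(0, n, dtype=float)

    f1 = float((p * p).sum())
    f2 = float((kd ** 2) @ p_diff)
    if sd_x > 0 and sd_y > 0:
        f3 = float(((I * J * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        f3 = 0.0
    f4 = float((((I - mu_x) ** 2) * p).sum())
    f5 = float((g["idm_w"] * p).sum())
    f6 = float(ks @ p_sum)
    f7 = float(((ks - f6) ** 2) @ p_sum)
    f8 = float(-_xlog2(p_sum).sum())
    f9 = float(-_xlog2(p).sum())
    mu_d = float(kd @ p_diff)
    f10 = float(((kd - mu_d) ** 2) @ p_diff)
    f11 = float(-_xlog2(p_diff).sum())

    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    pxpy = np.outer(px, py)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    hxy2 = float(-_xlog2(pxpy).sum())
    f12 = (f9 - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    f13 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - f9)))))

    return np.array([f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11, f12, f13])


# ---------------------------------------------------------------------------
# Per-VOI feature vectors
# ---------------------------------------------------------------------------

def feature_vector_for_voi(vol: Volume3D | np.ndarray, center: tuple[int, int, int],
                           window_size: int = WINDOW_DEFAULT,
                           distances: tuple[int, ...] = DISTANCES_DEFAULT,
                           n_levels: int = N_LEVELS_DEFAULT,
                           quantized: np.ndarray | None = None,
                           directions: DirectionSet | None = None) -> FeatureVector:
    """Texture descriptor of the window centered on one voxel of interest.

    The window is clipped at volume edges.  For each distance, 13 GLCMs
    (one per direction) are reduced to per-feature mean and population
    standard deviation across directions.  GLCMs with no valid pairs are
    excluded from the aggregation; if a distance has none, its 26 slots
    are zero.  Raises on a VOI whose window is entirely background.
    """
    Q = quantized if quantized is not None else quantize(vol, n_levels=n_levels)
    n_levels = int(max(n_levels, Q.max()))
    half = window_size // 2
    window = tuple((int(c) - half, int(c) + half + 1) for c in center)
    W = Q[_window_slices(window, Q.shape)]
    if not (W > 0).any():
        raise ValueError(f"empty VOI at {center}: window contains no foreground")
    dirs = directions if directions is not None else enumerate_directions_3d()

    out = np.empty(len(distances) * 26)
    pos = 0
    for d in distances:
        feats = []
        for off in dirs:
            disp = tuple(int(d * o) for o in off)
            flat = _pair_counts(W, disp, n_levels)
            total = flat.sum()
            if total == 0:
                continue
            counts = flat.reshape(n_levels, n_levels)
            counts = counts + counts.T
            m = GLCM(counts=counts / counts.sum(), n_levels=n_levels,
                     distance=d, offset=tuple(off), normalized=True)
            feats.append(haralick_features(m))
        if feats:
            F = np.array(feats)
            mean = F.mean(axis=0)
            std = F.std(axis=0)  # population std
        else:
            mean = np.zeros(13)
            std = np.zeros(13)
        out[pos:pos + 26:2] = mean
        out[pos + 1:pos + 26:2] = std
        pos += 26
    return FeatureVector(values=out, names=feature_names(tuple(distances)))


# ---------------------------------------------------------------------------
# Target area
# ---------------------------------------------------------------------------

_STRUCT_18 = ndimage.generate_binary_structure(3, 2)  # faces + edges


def extract_target_area(labels: LabelMap) -> np.ndarray:
    """VOI centers of the refinement target area.

    The target area is every overlap voxel plus its 18-connected
    neighbors (face- or edge-sharing), deduplicated and clipped to the
    grid.  Returns an (n, 3) integer index array in lexicographic order;
    empty when the overlap mask is empty.
    """
    mask = labels.overlap_mask
    if mask is None or not mask.any():
        return np.zeros((0, 3), dtype=np.intp)
    area = ndimage.binary_dilation(mask, structure=_STRUCT_18)
    return np.argwhere(area)
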