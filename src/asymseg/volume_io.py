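"""Volume and label-map I/O plus intensity histograms.

Volumes are 3-D scalar grids (T1-weighted MR intensities, assumed
skull-stripped and bias-corrected upstream) carried with their voxel
spacing and affine.  Label maps use the fixed tissue code table
``0=background, 1=CSF, 2=GM, 3=WM``.  NIfTI-1 (``.nii``/``.nii.gz``)
and Analyze 7.5 (``.hdr``/``.img``) are read through nibabel; writing
is NIfTI-1 only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "TISSUE_CODES",
    "Volume3D",
    "LabelMap",
    "Histogram",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "compute_histogram",
]

#: Fixed tissue code table used throughout the package.
TISSUE_CODES: dict[int, str] = {0: "BG", 1: "CSF", 2: "GM", 3: "WM"}

#: Tissue labels evaluated / segmented (background excluded).
FOREGROUND_LABELS: tuple[int, ...] = (1, 2, 3)


@dataclass
class Volume3D:
    """A 3-D scalar intensity volume with geometric metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities in scanner units; finite, nonnegative after
        preprocessing.
    spacing : tuple of float
        Voxel edge lengths (sx, sy, sz) in millimetres, strictly positive.
    affine : ndarray, shape (4, 4)
        Voxel-index to world-coordinate map.  Voxel indices are 0-based;
        world coordinates appear only at I/O boundaries.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3-D with all dims >= 1, got shape {self.data.shape}")
        if not all(s > 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LabelMap:
    """Integer tissue labels aligned with a :class:`Volume3D`.

    ``labels`` take values in {0, 1, 2, 3} (BG/CSF/GM/WM); ``overlap_mask``
    marks ambiguously labeled foreground voxels (the seed of the SVM
    refinement's target area) and is true only where the label is nonzero.
    """

    labels: np.ndarray
    overlap_mask: np.ndarray | None = None
    code_table: dict[int, str] = field(default_factory=lambda: dict(TISSUE_CODES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        bad = set(np.unique(self.labels)) - set(self.code_table)
        if bad:
            raise ValueError(f"unknown label codes {sorted(bad)}")
        if self.overlap_mask is None:
            self.overlap_mask = np.zeros(self.labels.shape, dtype=bool)
        else:
            self.overlap_mask = np.asarray(self.overlap_mask, dtype=bool)
            if self.overlap_mask.shape != self.labels.shape:
                raise ValueError("overlap_mask shape must match labels")
            if np.any(self.overlap_mask & (self.labels == 0)):
                raise ValueError("overlap_mask must be false on background voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def foreground(self) -> np.ndarray:
        """Boolean mask of non-background voxels."""
        return self.labels != 0


@dataclass
class Histogram:
    """Binned intensity histogram of foreground voxels.

    ``counts[i]`` is the number of voxels with intensity in
    ``[bin_edges[i], bin_edges[i+1])`` (last bin closed on the right).
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("bin_edges must have len(counts)+1 entries")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def slice(self, lo: int, hi: int) -> "Histogram":
        """Sub-histogram over bin index range [lo, hi)."""
        return Histogram(self.bin_edges[lo : hi + 1], self.counts[lo:hi])


# ---------------------------------------------------------------------------
# File I/O (nibabel)
# ---------------------------------------------------------------------------

def _load_image(path: str | os.PathLike) -> nib.spatialimages.SpatialImage:
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt header etc.
        raise ValueError(f"cannot parse {path!s} as NIfTI-1/Analyze: {exc}") from exc
    if not isinstance(img, (nib.Nifti1Image, nib.Nifti2Image, nib.AnalyzeImage)):
        raise ValueError(f"{path!s}: unsupported format {type(img).__name__}")
    return img


def _spacing_of(img: nib.spatialimages.SpatialImage) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)  # type: ignore[return-value]


def read_volume(path: str | os.PathLike) -> Volume3D:
    """Read a NIfTI-1 or Analyze 7.5 scalar volume.

    Intensities are returned unchanged (no scaling beyond the format's own
    scl_slope/scl_inter, which nibabel applies; integer data without scaling
    round-trips bit-identically).
    """
    img = _load_image(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path!s}: expected a 3-D volume, got shape {data.shape}")
    affine = img.affine if img.affine is not None else np.eye(4)
    return Volume3D(data=data, spacing=_spacing_of(img), affine=np.asarray(affine))


def write_volume(vol: Volume3D, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz by extension).

    Lossless for integer and 32-bit float data.
    """
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_labelmap(path: str | os.PathLike) -> LabelMap:
    """Read an integer NIfTI label volume using the fixed code table."""
    vol = read_volume(path)
    labels = np.asarray(vol.data)
    if not np.issubdtype(labels.dtype, np.integer):
        rounded = np.rint(labels)
        if not np.allclose(labels, rounded):
            raise ValueError(f"{path!s}: label volume has non-integer values")
        labels = rounded.astype(np.int16)
    return LabelMap(labels=labels.astype(np.int16, copy=False))


def write_labelmap(lab: LabelMap, path: str | os.PathLike,
                   spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                   affine: np.ndarray | None = None) -> None:
    """Write a label map as integer NIfTI."""
    vol = Volume3D(lab.labels.astype(np.int16, copy=False), spacing=spacing,
                   affine=np.eye(4) if affine is None else affine)
    write_volume(vol, path)


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------

def compute_histogram(vol: Volume3D, mask: LabelMap | np.ndarray | None = None,
                      n_bins: int = 256) -> Histogram:
    """Histogram of foreground intensities.

    With a mask (a :class:`LabelMap` or boolean array) only voxels where the
    label is nonzero (mask true) are counted.  Without one, exact-zero voxels
    are treated as background when they make up at least 1% of the volume —
    the convention for skull-stripped input with a zeroed exterior —
    otherwise every voxel counts.

    Bins are ``n_bins`` equal-width intervals spanning [min, max] of the
    counted intensities; the total count equals the number of counted voxels.
    """
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    data = vol.data
    if mask is not None:
        fg = mask.foreground() if isinstance(mask, LabelMap) else np.asarray(mask, dtype=bool)
        if fg.shape != data.shape:
            raise ValueError("mask shape must match volume")
    else:
        zero = data == 0
        fg = ~zero if zero.mean() >= 0.01 else np.ones(data.shape, dtype=bool)
    values = data[fg]
    if values.size == 0:
        raise ValueError("no foreground voxels")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        hi = lo + 1.0  # constant volume: all mass in the first bin
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    return Histogram(bin_edges=edges, counts=counts)
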