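"""CT preparation for radiomic analysis.

Covers the image-side plumbing of the slice-reduced CT (srCT) workflow:

* reduced-protocol handling — keeping only the six basal slice positions of
  the nine-slice protocol and picking the less noisy of the two duplicate
  slices acquired at every position,
* resampling — trilinear to isotropic voxel size for full-chest volumes,
  bilinear in-plane for 2D slice stacks,
* grey-level discretization with a fixed bin width over a fixed HU range.

Axis convention: arrays are (z, y, x) with z index 0 the most basal slice;
all physical positions are millimetres along the scanner axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

# Default grey-level discretization: fixed 50 HU bins over [-1000, 200] HU,
# i.e. 24 bins spanning aerated lung through soft tissue.
DEFAULT_BIN_WIDTH = 50.0
DEFAULT_HU_RANGE = (-1000.0, 200.0)

# Reduced protocol geometry: six basal positions, 15 mm apart.
LOWER_SUBSCAN_POSITIONS = 6
LOWER_SUBSCAN_SPACING_MM = 15.0


class PreprocessError(ValueError):
    """Raised when an image-preparation contract is violated."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class CTVolume:
    """A 3D grid of Hounsfield-unit intensities with physical geometry.

    Parameters
    ----------
    intensities
        HU array of shape (z, y, x).
    spacing
        Voxel spacing in mm, ordered (z, y, x).
    slice_positions
        Physical position of each axial slice in mm; strictly monotone,
        index 0 = most basal slice.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    slice_positions: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.ndim != 3:
            raise PreprocessError("CTVolume expects a (z, y, x) array")
        if any(s <= 0 for s in self.spacing):
            raise PreprocessError("voxel spacing must be positive")
        if self.slice_positions is None:
            self.slice_positions = np.arange(self.intensities.shape[0]) * self.spacing[0]
        self.slice_positions = np.asarray(self.slice_positions, dtype=float)
        if self.slice_positions.shape[0] != self.intensities.shape[0]:
            raise PreprocessError("one slice position per axial slice required")
        d = np.diff(self.slice_positions)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise PreprocessError("slice positions must be strictly monotone")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]


@dataclass
class ROIMask:
    """Binary mask aligned voxel-for-voxel to a :class:`CTVolume`."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def check_aligned(self, volume: CTVolume) -> None:
        if self.mask.shape != volume.shape:
            raise PreprocessError(
                f"mask shape {self.mask.shape} does not match volume {volume.shape}"
            )


@dataclass
class ProtocolSlice:
    """One slice position of the reduced protocol.

    Every position is acquired twice (a scanner constraint), so carries two
    duplicate 2D HU arrays sharing the anatomy but with independent noise.
    """

    position: float          # mm along the scanner axis
    sub_scan: str            # "upper" or "lower"
    duplicates: list[np.ndarray]
    mask: np.ndarray         # 2D lung mask at this position

    def __post_init__(self) -> None:
        self.duplicates = [np.asarray(d, dtype=np.float32) for d in self.duplicates]
        self.mask = np.asarray(self.mask).astype(bool)
        for d in self.duplicates:
            if d.shape != self.mask.shape:
                raise PreprocessError("duplicate slice and mask shapes differ")


@dataclass
class SliceProtocol:
    """A reduced-CT acquisition: slice positions with sub-scan membership."""

    slices: list[ProtocolSlice]
    pixel_spacing: tuple[float, float]   # mm (y, x)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.slices], dtype=float)

    def sub_scan_slices(self, tag: str) -> list[ProtocolSlice]:
        return [s for s in self.slices if s.sub_scan == tag]


@dataclass
class DiscretizedImage:
    """Grey-level discretized image: integer bins 1..n_bins inside the ROI.

    Voxels outside the ROI are coded 0 and carry no meaning.
    """

    bins: np.ndarray
    n_bins: int
    roi: np.ndarray
    bin_width: float | None = None
    hu_range: tuple[float, float] | None = None

    def roi_bins(self) -> np.ndarray:
        """In-ROI bin values, flattened."""
        return self.bins[self.roi]


# ---------------------------------------------------------------------------
# Reduced-protocol slice handling
# ---------------------------------------------------------------------------

def select_bottom_positions(protocol: SliceProtocol) -> SliceProtocol:
    """Keep only the six lower-sub-scan positions of a reduced protocol.

    The upper sub-scan is discarded unconditionally — even when an upper
    slice sits physically below a lower one — so that the retained stack
    always consists of the six basal positions with their fixed 15 mm
    spacing. Idempotent.
    """
    lower = sorted(protocol.sub_scan_slices("lower"), key=lambda s: s.position)
    if len(lower) != LOWER_SUBSCAN_POSITIONS:
        raise PreprocessError(
            f"expected a {LOWER_SUBSCAN_POSITIONS}-position lower sub-scan, "
            f"found {len(lower)} positions"
        )
    gaps = np.diff([s.position for s in lower])
    if not np.allclose(gaps, gaps[0]):
        raise PreprocessError("lower sub-scan positions are not equally spaced")
    return SliceProtocol(slices=lower, pixel_spacing=protocol.pixel_spacing)


def snr(slice_2d: np.ndarray, roi: np.ndarray) -> float:
    """Signal-to-noise ratio of a slice inside an ROI: ``|mean| / sd``.

    Higher means less noisy. A zero-variance slice is noise-free by this
    definition and returns ``inf``.
    """
    slice_2d = np.asarray(slice_2d, dtype=float)
    roi = np.asarray(roi).astype(bool)
    if slice_2d.shape != roi.shape:
        raise PreprocessError("slice and ROI shapes differ")
    vals = slice_2d[roi]
    if vals.size == 0:
        raise PreprocessError("empty ROI")
    sd = float(vals.std())
    if sd == 0.0:
        return math.inf
    return abs(float(vals.mean())) / sd


def select_less_noisy_duplicate(
    dup_a: np.ndarray, dup_b: np.ndarray, roi: np.ndarray
) -> np.ndarray:
    """Of two duplicate slices of one position, return the higher-SNR one.

    Ties (including both noise-free) go to the first-listed duplicate, so
    the choice is deterministic.
    """
    dup_a = np.asarray(dup_a)
    dup_b = np.asarray(dup_b)
    if dup_a.shape != dup_b.shape:
        raise PreprocessError("duplicate slices have mismatched shapes")
    return dup_a if snr(dup_a, roi) >= snr(dup_b, roi) else dup_b


def resolve_protocol(protocol: SliceProtocol) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Apply basal selection and per-position SNR duplicate choice.

    Returns (slices, masks, positions) for the six retained basal positions,
    base first.
    """
    lower = select_bottom_positions(protocol)
    chosen = [
        select_less_noisy_duplicate(s.duplicates[0], s.duplicates[1], s.mask)
        for s in lower.slices
    ]
    masks = [s.mask for s in lower.slices]
    return chosen, masks, lower.positions


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _zoom_intensity(arr: np.ndarray, factors: Sequence[float]) -> np.ndarray:
    # order=1 (tri/bilinear): monotone, no ringing at the air boundary.
    return ndimage.zoom(
        np.asarray(arr, dtype=np.float32), factors, order=1,
        mode="nearest", grid_mode=True,
    )


def _zoom_mask(mask: np.ndarray, factors: Sequence[float]) -> np.ndarray:
    # Linear interpolation of the indicator then 0.5 threshold keeps the
    # resampled mask partial-volume consistent.
    dense = ndimage.zoom(
        np.asarray(mask, dtype=np.float32), factors, order=1,
        mode="nearest", grid_mode=True,
    )
    return dense >= 0.5


def resample_3d(
    volume: CTVolume,
    mask: ROIMask,
    target_spacing: float | tuple[float, float, float],
) -> tuple[CTVolume, ROIMask]:
    """Resample a volume/mask pair to a (typically isotropic) voxel size.

    Intensities are interpolated trilinearly; the mask linearly then
    thresholded at 0.5.
    """
    if np.isscalar(target_spacing):
        target = (float(target_spacing),) * 3
    else:
        target = tuple(float(t) for t in target_spacing)  # type: ignore[arg-type]
    if any(t <= 0 for t in target):
        raise PreprocessError("target spacing must be positive")
    mask.check_aligned(volume)
    factors = [s / t for s, t in zip(volume.spacing, target)]
    out = _zoom_intensity(volume.intensities, factors)
    new_mask = _zoom_mask(mask.mask, factors)
    z0 = float(volume.slice_positions[0])
    positions = z0 + np.arange(out.shape[0]) * target[0]
    return (
        CTVolume(out, spacing=target, slice_positions=positions),
        ROIMask(new_mask),
    )


def resample_inplane_2d(
    slices: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    pixel_spacing: tuple[float, float],
    target_pixel: float,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Resample each 2D slice (and mask) in-plane to a square pixel size.

    Slice thickness and z geometry are untouched; only the (y, x) grid
    changes. Bilinear for intensities, linear + 0.5 threshold for masks.
    """
    if target_pixel <= 0:
        raise PreprocessError("target pixel size must be positive")
    factors = [pixel_spacing[0] / target_pixel, pixel_spacing[1] / target_pixel]
    out_slices, out_masks = [], []
    for sl, m in zip(slices, masks):
        if np.allclose(factors, 1.0):
            out_slices.append(np.asarray(sl, dtype=np.float32).copy())
            out_masks.append(np.asarray(m).astype(bool).copy())
        else:
            out_slices.append(_zoom_intensity(sl, factors))
            out_masks.append(_zoom_mask(m, factors))
    return out_slices, out_masks


# ---------------------------------------------------------------------------
# Grey-level discretization
# ---------------------------------------------------------------------------

def discretize(
    image: np.ndarray,
    roi: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    hu_range: tuple[float, float] = DEFAULT_HU_RANGE,
) -> DiscretizedImage:
    """Fixed-bin-width grey-level discretization over a fixed HU range.

    ``bin(x) = floor((clip(x, lo, hi) - lo) / width) + 1``, with the upper
    range limit mapped into the top bin, yielding bins 1..24 for the default
    50 HU bins over [-1000, 200]. Out-of-range values are clipped, not
    dropped, so the in-ROI voxel count is identical before and after.
    """
    if bin_width <= 0:
        raise PreprocessError("bin width must be positive")
    lo, hi = float(hu_range[0]), float(hu_range[1])
    if hi <= lo:
        raise PreprocessError("empty HU range")
    roi = np.asarray(roi).astype(bool)
    image = np.asarray(image, dtype=float)
    if image.shape != roi.shape:
        raise PreprocessError("image and ROI shapes differ")
    if not roi.any():
        raise PreprocessError("empty ROI")
    n_bins = int(math.ceil((hi - lo) / bin_width))
    clipped = np.clip(image, lo, hi)
    bins = np.floor((clipped - lo) / bin_width).astype(np.int64) + 1
    bins = np.clip(bins, 1, n_bins)     # maps x == hi into the top bin
    bins[~roi] = 0
    return DiscretizedImage(bins=bins, n_bins=n_bins, roi=roi,
                            bin_width=bin_width, hu_range=(lo, hi))


def discretize_fixed_count(
    image: np.ndarray, roi: np.ndarray, n_bins: int = 24
) -> DiscretizedImage:
    """Fixed-bin-count discretization over the in-ROI intensity range.

    Used for wavelet sub-band images, whose values no longer live on the HU
    scale, so fixed HU bin edges would be meaningless. A constant in-ROI
    image maps entirely to bin 1.
    """
    if n_bins < 1:
        raise PreprocessError("need at least one bin")
    roi = np.asarray(roi).astype(bool)
    image = np.asarray(image, dtype=float)
    if not roi.any():
        raise PreprocessError("empty ROI")
    vals = image[roi]
    lo, hi = float(vals.min()), float(vals.max())
    bins = np.zeros(image.shape, dtype=np.int64)
    if hi == lo:
        bins[roi] = 1
    else:
        scaled = np.floor((image - lo) / (hi - lo) * n_bins).astype(np.int64) + 1
        bins = np.clip(scaled, 1, n_bins)
        bins[~roi] = 0
    return DiscretizedImage(bins=bins, n_bins=n_bins, roi=roi)
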