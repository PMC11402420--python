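"""Radiomic feature extraction: intensity histogram, GLCM, GLSZM, wavelets.

Three feature families are computed on the original image and on every
sub-band of a single-level decimated wavelet transform, in 2D (per slice,
averaged over the slices of a reduced stack) and in 3D (whole volume):

* intensity-histogram statistics on continuous HU values,
* grey-level co-occurrence matrix (GLCM) statistics on the discretized
  image, with symmetric accumulation merged over all directions
  (4 in-plane in 2D, 13 in 3D) before normalization,
* grey-level size-zone matrix (GLSZM) statistics with 8-connectivity per
  slice in 2D and 26-connectivity in 3D.

Texture is computed on the 24-bin fixed-bin-width discretization; wavelet
sub-bands are re-discretized to a fixed bin count since HU bin edges are
meaningless after filtering. Definitions follow the image biomarker
standardization conventions.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage

from .ct_preprocess import (
    DiscretizedImage,
    CTVolume,
    ROIMask,
    PreprocessError,
    discretize,
    discretize_fixed_count,
    resample_3d,
    resample_inplane_2d,
    resolve_protocol,
)
from .synthetic_cohort import SyntheticPatient

WAVELET = "coif1"
WAVELET_MODE = "symmetric"
SUBBAND_N_BINS = 24

# Offsets covering half of each symmetric direction pair; symmetric
# accumulation adds the reverse offset implicitly.
DIRECTIONS_2D: list[tuple[int, int]] = [(0, 1), (1, 0), (1, 1), (1, -1)]
DIRECTIONS_3D: list[tuple[int, int, int]] = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureDescriptor:
    """Provenance of one feature column."""

    name: str                 # e.g. "LL_GLCM_clusterShade"
    family: str               # intensity | GLCM | GLSZM
    sub_band: str             # original, LL..HH, LLL..HHH
    space: str                # 2D | 3D


@dataclass
class FeatureTable:
    """Patients x features with per-column provenance."""

    values: pd.DataFrame
    descriptors: list[FeatureDescriptor]
    labels: pd.Series
    space: str
    resolution: float

    def __post_init__(self) -> None:
        names = [d.name for d in self.descriptors]
        if names != list(self.values.columns):
            raise FeatureError("descriptors do not match table columns")
        if len(names) != len(set(names)):
            raise FeatureError("duplicate feature names")

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="patient_id")

    def descriptor_records(self) -> list[dict]:
        return [vars(d) for d in self.descriptors]


# ---------------------------------------------------------------------------
# Intensity histogram family
# ---------------------------------------------------------------------------

def intensity_stats(values: np.ndarray) -> "OrderedDict[str, float]":
    """First-order statistics of the in-ROI HU distribution.

    Moments are population moments (``sd`` divides by N); ``kurtosis`` is
    the non-excess Pearson kurtosis, so a Gaussian scores 3. Zero-variance
    input leaves skewness and kurtosis undefined (NaN), which the cleaning
    stage later removes.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise FeatureError("need at least two values for intensity statistics")
    m = float(x.mean())
    d = x - m
    m2 = float(np.mean(d**2))
    sd = float(np.sqrt(m2))
    if m2 > 0:
        skew = float(np.mean(d**3)) / m2**1.5
        kurt = float(np.mean(d**4)) / m2**2
    else:
        skew = float("nan")
        kurt = float("nan")
    q = np.percentile(x, [10, 25, 50, 75, 90])
    return OrderedDict(
        [
            ("hist_mean", m),
            ("hist_sd", sd),
            ("hist_skewness", skew),
            ("hist_kurtosis", kurt),
            ("hist_median", float(q[2])),
            ("hist_p10", float(q[0])),
            ("hist_p90", float(q[4])),
            ("hist_iqr", float(q[3] - q[1])),
            ("hist_range", float(x.max() - x.min())),
            ("hist_mad", float(np.mean(np.abs(d)))),
        ]
    )


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

@dataclass
class GLCMatrix:
    """Symmetric joint probability over grey-level pairs, merged over directions."""

    p: np.ndarray     # (n_bins, n_bins), sums to 1
    n_bins: int


def glcm(
    disc: DiscretizedImage,
    distance: int = 1,
    directions: Sequence[tuple[int, ...]] | None = None,
) -> GLCMatrix:
    """Co-occurrence counts of in-ROI neighbour pairs.

    Both voxels of a pair must lie inside the ROI. Counts are accumulated
    symmetrically (each ordered pair and its reverse) and merged over all
    directions before normalization.
    """
    bins, roi, n = disc.bins, disc.roi, disc.n_bins
    if directions is None:
        directions = DIRECTIONS_2D if bins.ndim == 2 else DIRECTIONS_3D
    counts = np.zeros((n, n), dtype=np.int64)
    for off in directions:
        off = tuple(int(o) * distance for o in off)
        src = tuple(
            slice(max(-o, 0), bins.shape[ax] - max(o, 0))
            for ax, o in enumerate(off)
        )
        dst = tuple(
            slice(max(o, 0), bins.shape[ax] + min(o, 0))
            for ax, o in enumerate(off)
        )
        a, b = bins[src], bins[dst]
        valid = roi[src] & roi[dst]
        ai, bi = a[valid] - 1, b[valid] - 1
        np.add.at(counts, (ai, bi), 1)
        np.add.at(counts, (bi, ai), 1)
    total = counts.sum()
    if total == 0:
        raise FeatureError("ROI has no in-ROI neighbouring voxel pairs")
    return GLCMatrix(p=counts / total, n_bins=n)


def glcm_sum_variance(P: GLCMatrix) -> float:
    """Variance of the diagonal-sum distribution p_{x+y}."""
    pxy = _p_sum(P)
    k = np.arange(2, 2 * P.n_bins + 1)
    sa = float((k * pxy).sum())
    return float((((k - sa) ** 2) * pxy).sum())


def glcm_cluster_shade(P: GLCMatrix) -> float:
    """Third central moment of i + j about mu_x + mu_y (skew of clustering)."""
    i = np.arange(1, P.n_bins + 1)
    mu = float((P.p.sum(axis=1) * i).sum())   # symmetric: mu_x = mu_y
    ii, jj = np.meshgrid(i, i, indexing="ij")
    return float((((ii + jj - 2 * mu) ** 3) * P.p).sum())


def _p_sum(P: GLCMatrix) -> np.ndarray:
    """Diagonal-sum marginal p_{x+y}; index 0 corresponds to i + j = 2."""
    n = P.n_bins
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    return np.bincount(
        (ii + jj).ravel() - 2, weights=P.p.ravel(), minlength=2 * n - 1
    )


def glcm_features(P: GLCMatrix) -> "OrderedDict[str, float]":
    p = P.p
    n = P.n_bins
    i = np.arange(1, n + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((px * i).sum())
    var = float((px * (i - mu) ** 2).sum())
    nz = p > 0

    pxy = _p_sum(P)
    ks = np.arange(2, 2 * n + 1, dtype=float)
    sa = float((ks * pxy).sum())
    pd_ = np.bincount(
        np.abs(ii - jj).astype(int).ravel(), weights=p.ravel(), minlength=n
    )
    kd = np.arange(0, n, dtype=float)
    da = float((kd * pd_).sum())

    feats: "OrderedDict[str, float]" = OrderedDict()
    feats["jointMax"] = float(p.max())
    feats["jointAverage"] = mu
    feats["jointVariance"] = float((((ii - mu) ** 2) * p).sum())
    feats["jointEntropy"] = float(-(p[nz] * np.log2(p[nz])).sum())
    feats["energy"] = float((p**2).sum())
    feats["contrast"] = float((((ii - jj) ** 2) * p).sum())
    feats["dissimilarity"] = float((np.abs(ii - jj) * p).sum())
    feats["inverseDifference"] = float((p / (1.0 + np.abs(ii - jj))).sum())
    feats["inverseDifferenceMoment"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    off = ii != jj
    feats["inverseVariance"] = float((p[off] / ((ii - jj)[off] ** 2)).sum())
    if var > 0:
        feats["correlation"] = float(
            (((ii - mu) * (jj - mu) * p).sum()) / var
        )
    else:
        feats["correlation"] = 1.0
    feats["autocorrelation"] = float((ii * jj * p).sum())
    feats["clusterTendency"] = float((((ii + jj - 2 * mu) ** 2) * p).sum())
    feats["clusterShade"] = float((((ii + jj - 2 * mu) ** 3) * p).sum())
    feats["clusterProminence"] = float((((ii + jj - 2 * mu) ** 4) * p).sum())
    feats["sumAverage"] = sa
    feats["sumVariance"] = float((((ks - sa) ** 2) * pxy).sum())
    nzs = pxy > 0
    feats["sumEntropy"] = float(-(pxy[nzs] * np.log2(pxy[nzs])).sum())
    feats["differenceAverage"] = da
    feats["differenceVariance"] = float((((kd - da) ** 2) * pd_).sum())
    nzd = pd_ > 0
    feats["differenceEntropy"] = float(-(pd_[nzd] * np.log2(pd_[nzd])).sum())
    return feats


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

@dataclass
class GLSZMatrix:
    """Zone counts s(i, z): maximal connected zones of grey level i, size z."""

    s: np.ndarray        # (n_bins, max_zone_size)
    n_bins: int
    n_roi_voxels: int

    @property
    def n_zones(self) -> int:
        return int(self.s.sum())

    def p(self) -> np.ndarray:
        return self.s / self.s.sum()


def glszm(disc: DiscretizedImage) -> GLSZMatrix:
    """Size-zone matrix: 8-connectivity in 2D, 26-connectivity in 3D."""
    bins, roi, n = disc.bins, disc.roi, disc.n_bins
    if not roi.any():
        raise FeatureError("empty ROI")
    structure = np.ones((3,) * bins.ndim, dtype=bool)
    sizes_by_level: list[tuple[int, np.ndarray]] = []
    max_size = 0
    for level in range(1, n + 1):
        lab, n_lab = ndimage.label((bins == level) & roi, structure=structure)
        if n_lab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        sizes_by_level.append((level, sizes))
        max_size = max(max_size, int(sizes.max()))
    s = np.zeros((n, max_size), dtype=np.int64)
    for level, sizes in sizes_by_level:
        for size in sizes:
            s[level - 1, size - 1] += 1
    return GLSZMatrix(s=s, n_bins=n, n_roi_voxels=int(roi.sum()))


def glszm_zone_size_entropy(S: GLSZMatrix) -> float:
    """Shannon entropy (bits) of the normalized zone matrix."""
    p = S.p().ravel()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glszm_features(S: GLSZMatrix) -> "OrderedDict[str, float]":
    s = S.s.astype(float)
    ns = s.sum()
    p = s / ns
    n_bins, max_z = s.shape
    i = np.arange(1, n_bins + 1, dtype=float)[:, None]
    z = np.arange(1, max_z + 1, dtype=float)[None, :]

    si = s.sum(axis=1)   # zones per grey level
    sz = s.sum(axis=0)   # zones per size

    feats: "OrderedDict[str, float]" = OrderedDict()
    feats["smallZoneEmphasis"] = float((s / z**2).sum() / ns)
    feats["largeZoneEmphasis"] = float((s * z**2).sum() / ns)
    feats["lowGreyLevelZoneEmphasis"] = float((s / i**2).sum() / ns)
    feats["highGreyLevelZoneEmphasis"] = float((s * i**2).sum() / ns)
    feats["smallZoneLowGreyLevelEmphasis"] = float((s / (i**2 * z**2)).sum() / ns)
    feats["smallZoneHighGreyLevelEmphasis"] = float((s * i**2 / z**2).sum() / ns)
    feats["largeZoneLowGreyLevelEmphasis"] = float((s * z**2 / i**2).sum() / ns)
    feats["largeZoneHighGreyLevelEmphasis"] = float((s * i**2 * z**2).sum() / ns)
    feats["greyLevelNonUniformity"] = float((si**2).sum() / ns)
    feats["greyLevelNonUniformityNormalized"] = float((si**2).sum() / ns**2)
    feats["zoneSizeNonUniformity"] = float((sz**2).sum() / ns)
    feats["zoneSizeNonUniformityNormalized"] = float((sz**2).sum() / ns**2)
    feats["zonePercentage"] = float(ns / S.n_roi_voxels)
    mu_i = float((p * i).sum())
    feats["greyLevelVariance"] = float((p * (i - mu_i) ** 2).sum())
    mu_z = float((p * z).sum())
    feats["zoneSizeVariance"] = float((p * (z - mu_z) ** 2).sum())
    feats["zsEntropy"] = glszm_zone_size_entropy(S)
    return feats


# ---------------------------------------------------------------------------
# Wavelet decomposition
# ---------------------------------------------------------------------------

def wavelet_decompose(
    image: np.ndarray, wavelet: str = WAVELET
) -> "OrderedDict[str, np.ndarray]":
    """Single-level separable decimated wavelet transform.

    Returns sub-bands named by one L (low-pass) or H (high-pass) letter per
    axis in (z, )y, x order: 4 sub-bands for a 2D slice, 8 for a 3D volume.
    Symmetric boundary padding.
    """
    image = np.asarray(image, dtype=float)
    w = pywt.Wavelet(wavelet)
    if min(image.shape) < w.dec_len:
        raise FeatureError(
            f"image shape {image.shape} smaller than the {wavelet} filter support"
        )
    coeffs = pywt.dwtn(image, w, mode=WAVELET_MODE)
    out: "OrderedDict[str, np.ndarray]" = OrderedDict()
    for key in sorted(coeffs, key=lambda k: (k.count("d"), k)):
        name = key.replace("a", "L").replace("d", "H")
        out[name] = coeffs[key]
    return out


def _downsample_mask(mask: np.ndarray, target_shape: tuple[int, ...]) -> np.ndarray:
    """Resize an ROI mask to a (roughly halved) wavelet sub-band grid."""
    factors = [t / s for t, s in zip(target_shape, mask.shape)]
    dense = ndimage.zoom(mask.astype(np.float32), factors, order=1,
                         mode="nearest", grid_mode=True)
    out = dense >= 0.5
    if not out.any() and mask.any():
        out = dense > 0
    return out


# ---------------------------------------------------------------------------
# Per-image feature block
# ---------------------------------------------------------------------------

def _texture_block(disc: DiscretizedImage) -> "OrderedDict[str, float]":
    out: "OrderedDict[str, float]" = OrderedDict()
    P = glcm(disc)
    for k, v in glcm_features(P).items():
        out[f"GLCM_{k}"] = v
    S = glszm(disc)
    for k, v in glszm_features(S).items():
        out[f"GLSZM_{k}"] = v
    return out


def _image_features(
    image: np.ndarray,
    roi: np.ndarray,
    bin_width: float,
    hu_range: tuple[float, float],
    wavelet: str,
) -> "OrderedDict[str, float]":
    """All families on the original image and every wavelet sub-band.

    Column order is intensity, then texture, then all wavelet features —
    the extraction order the downstream ranking option relies on.
    """
    feats: "OrderedDict[str, float]" = OrderedDict()
    for k, v in intensity_stats(image[roi]).items():
        feats[f"original_{k}"] = v
    disc = discretize(image, roi, bin_width=bin_width, hu_range=hu_range)
    for k, v in _texture_block(disc).items():
        feats[f"original_{k}"] = v
    for band, sub in wavelet_decompose(image, wavelet=wavelet).items():
        sub_roi = _downsample_mask(roi, sub.shape)
        if sub_roi.sum() < 2:
            raise FeatureError("ROI vanished on a wavelet sub-band grid")
        for k, v in intensity_stats(sub[sub_roi]).items():
            feats[f"{band}_{k}"] = v
        sub_disc = discretize_fixed_count(sub, sub_roi, n_bins=SUBBAND_N_BINS)
        for k, v in _texture_block(sub_disc).items():
            feats[f"{band}_{k}"] = v
    return feats


def _descriptors_from_names(names: Iterable[str], space: str) -> list[FeatureDescriptor]:
    out = []
    for name in names:
        band, family, _ = name.split("_", 2)
        fam = {"hist": "intensity", "GLCM": "GLCM", "GLSZM": "GLSZM"}[family]
        out.append(FeatureDescriptor(name=name, family=fam, sub_band=band, space=space))
    return out


# ---------------------------------------------------------------------------
# Patient-level extraction
# ---------------------------------------------------------------------------

def extract_features_3d(
    volume: CTVolume,
    mask: ROIMask,
    target_spacing: float = 2.0,
    bin_width: float = 50.0,
    hu_range: tuple[float, float] = (-1000.0, 200.0),
    wavelet: str = WAVELET,
    intensity_only: bool = False,
) -> "OrderedDict[str, float]":
    """3D features on a full-chest volume resampled to isotropic spacing."""
    vol, m = resample_3d(volume, mask, target_spacing)
    roi = m.mask
    if roi.sum() < 2:
        raise FeatureError("ROI empty after resampling")
    if intensity_only:
        feats: "OrderedDict[str, float]" = OrderedDict()
        for k, v in intensity_stats(vol.intensities[roi]).items():
            feats[f"original_{k}"] = v
        return feats
    return _image_features(vol.intensities, roi, bin_width, hu_range, wavelet)


def extract_features_2d(
    patient_stack,
    target_pixel: float = 0.72,
    bin_width: float = 50.0,
    hu_range: tuple[float, float] = (-1000.0, 200.0),
    wavelet: str = WAVELET,
    intensity_only: bool = False,
) -> "OrderedDict[str, float]":
    """2D features on the resolved reduced stack, averaged over slices.

    The stack is first reduced to the six basal positions with the less
    noisy duplicate per position, then resampled in-plane. Each feature is
    computed per slice and averaged over slices containing ROI pixels.
    """
    slices, masks, _ = resolve_protocol(patient_stack)
    slices, masks = resample_inplane_2d(
        slices, masks, patient_stack.pixel_spacing, target_pixel
    )
    rows = []
    for sl, m in zip(slices, masks):
        if m.sum() < 2:
            continue
        if intensity_only:
            row: "OrderedDict[str, float]" = OrderedDict()
            for k, v in intensity_stats(sl[m]).items():
                row[f"original_{k}"] = v
        else:
            row = _image_features(sl, m, bin_width, hu_range, wavelet)
        rows.append(row)
    if not rows:
        raise FeatureError("no slice with ROI pixels in the reduced stack")
    keys = list(rows[0].keys())
    return OrderedDict(
        (k, float(np.mean([r[k] for r in rows]))) for k in keys
    )


def extract_features(
    patient: SyntheticPatient,
    space: Literal["2D", "3D"],
    resolution: float,
    intensity_only: bool = False,
    bin_width: float = 50.0,
    hu_range: tuple[float, float] = (-1000.0, 200.0),
    wavelet: str = WAVELET,
) -> "OrderedDict[str, float]":
    """One patient's feature row for a given image space and resolution."""
    if patient.fc_mask.n_voxels == 0:
        raise FeatureError("patient has no ROI voxels")
    if space == "3D":
        return extract_features_3d(
            patient.fc_volume, patient.fc_mask, target_spacing=resolution,
            bin_width=bin_width, hu_range=hu_range, wavelet=wavelet,
            intensity_only=intensity_only,
        )
    if space == "2D":
        return extract_features_2d(
            patient.sr_stack, target_pixel=resolution,
            bin_width=bin_width, hu_range=hu_range, wavelet=wavelet,
            intensity_only=intensity_only,
        )
    raise FeatureError(f"unknown space {space!r}")


def build_feature_table(
    patients: Sequence[SyntheticPatient],
    space: Literal["2D", "3D"],
    resolution: float,
    intensity_only: bool = False,
    **kwargs,
) -> FeatureTable:
    """Extract one row per patient into a :class:`FeatureTable`."""
    rows = [
        extract_features(p, space, resolution, intensity_only=intensity_only, **kwargs)
        for p in patients
    ]
    ids = [p.patient_id for p in patients]
    values = pd.DataFrame(rows, index=ids)
    labels = pd.Series([p.label for p in patients], index=ids, name="label")
    descriptors = _descriptors_from_names(values.columns, space)
    return FeatureTable(
        values=values, descriptors=descriptors,
        labels=labels, space=space, resolution=resolution,
    )


# Named intensity columns of the predefined quantitative-CT models.
QCT_M_FEATURES = ["original_hist_mean"]
QCT_MSDSK_FEATURES = [
    "original_hist_mean",
    "original_hist_sd",
    "original_hist_skewness",
    "original_hist_kurtosis",
]
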