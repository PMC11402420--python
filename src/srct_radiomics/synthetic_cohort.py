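"""Seeded synthetic cohorts of systemic-sclerosis ILD chest CT.

The real study population (166 patients: 99 without interstitial lung
disease, 44 with limited and 23 with extensive involvement by the Goh
< 20 % / > 20 % extent criterion) is not publicly deposited. This module
generates cohorts with the statistical structure the downstream analysis
relies on, so every stage is testable without any download:

* two half-ellipsoid lungs with a flattened base inside a full-chest volume,
* fibrosis-like disease regions: a correlated Gaussian random field,
  weighted toward the lung base by a logistic ramp, thresholded at the
  quantile that yields the target extent fraction, with elevated mean
  attenuation and coarser texture than healthy parenchyma,
* a nine-slice reduced protocol per patient: an upper sub-scan of three
  positions and a lower sub-scan of six positions spaced exactly 15 mm,
  every position acquired twice with independent noise at two levels
  (randomized order), so duplicate-selection logic is exercised.

Identical (config, seed) pairs produce bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import ndimage

from .ct_preprocess import (
    CTVolume,
    ProtocolSlice,
    ROIMask,
    SliceProtocol,
    LOWER_SUBSCAN_POSITIONS,
    LOWER_SUBSCAN_SPACING_MM,
)

LABELS = ("none", "limited", "extensive")
Label = Literal["none", "limited", "extensive"]

# Texture amplitudes (HU). Healthy parenchyma varies mildly around its mean;
# fibrotic regions are markedly more heterogeneous, which is what makes the
# disease texture detectable by co-occurrence / size-zone statistics and not
# only by the mean attenuation shift.
HEALTHY_TEXTURE_SD = 35.0
DISEASE_TEXTURE_SD = 90.0

UPPER_SUBSCAN_POSITIONS = 3
UPPER_SUBSCAN_SPACING_MM = 21.0


class GenerationError(RuntimeError):
    """Raised when a cohort cannot be generated under the given config."""


class CohortConfig(BaseModel):
    """Configuration of a synthetic cohort.

    Defaults mirror the study population: 99 / 44 / 23 patients without /
    with limited / with extensive disease, the 20 % extent threshold
    separating limited from extensive, parenchymal HU around -850 and
    diseased tissue around -400, and a reduced protocol with duplicate
    slices at two noise levels.
    """

    model_config = ConfigDict(extra="forbid")

    n_none: int = Field(default=99, ge=0)
    n_limited: int = Field(default=44, ge=0)
    n_extensive: int = Field(default=23, ge=0)
    volume_shape: tuple[int, int, int] = (64, 64, 64)          # voxels (z,y,x)
    voxel_spacing: tuple[float, float, float] = (3.0, 2.5, 2.5)  # mm (z,y,x)
    disease_extent_limited: float = Field(default=0.12, gt=0.0, lt=0.20)
    disease_extent_extensive: float = Field(default=0.40, gt=0.20, lt=0.60)
    basal_gradient_strength: float = Field(default=6.0, ge=0.0)
    healthy_mean_hu: float = -850.0
    disease_mean_hu: float = -400.0
    noise_sd_low: float = Field(default=20.0, ge=0.0)
    noise_sd_high: float = Field(default=60.0, ge=0.0)
    texture_correlation_length: float = Field(default=6.0, gt=0.0)  # mm
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        if any(s < 8 for s in self.volume_shape):
            raise ValueError("volume_shape too small for a lung phantom")
        if self.noise_sd_low > self.noise_sd_high:
            raise ValueError("noise_sd_low must not exceed noise_sd_high")
        step_vox = LOWER_SUBSCAN_SPACING_MM / self.voxel_spacing[0]
        if abs(step_vox - round(step_vox)) > 1e-9 or round(step_vox) < 1:
            raise ValueError(
                "z voxel spacing must divide the 15 mm protocol spacing so "
                "reduced slices fall on exact volume planes"
            )
        return self

    @property
    def n_total(self) -> int:
        return self.n_none + self.n_limited + self.n_extensive


@dataclass
class SyntheticPatient:
    """One synthetic patient: full-chest volume, reduced stack, labels."""

    patient_id: str
    label: Label
    fc_volume: CTVolume
    fc_mask: ROIMask
    fc_disease_mask: np.ndarray          # boolean, aligned to fc_volume
    sr_stack: SliceProtocol
    true_disease_fraction: float


# ---------------------------------------------------------------------------
# Geometry and fields
# ---------------------------------------------------------------------------

def lung_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Two half-ellipsoid lungs with a flattened base.

    Anatomical realism (airways, vessels, mediastinum) is deliberately out
    of scope: masks are inputs to the real pipeline, the phantom only has to
    give the texture statistics somewhere plausible to live.
    """
    nz, ny, nx = shape
    z, y, x = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    cz, cy = 0.50 * nz, 0.50 * ny
    rz, ry, rx = 0.42 * nz, 0.30 * ny, 0.17 * nx
    base_cut = cz - 0.75 * rz
    mask = np.zeros(shape, dtype=bool)
    for cx in (0.28 * nx, 0.72 * nx):
        ell = (
            ((z - cz) / rz) ** 2 + ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2
        ) <= 1.0
        mask |= ell
    mask &= z >= base_cut
    return mask


def _correlated_field(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    correlation_length_mm: float,
) -> np.ndarray:
    """Unit-variance Gaussian random field, smoothed to a correlation length."""
    white = rng.standard_normal(shape)
    sigma_vox = [correlation_length_mm / (2.0 * s) for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = smooth.std()
    if sd == 0:
        return smooth
    return (smooth - smooth.mean()) / sd


def _basal_ramp(shape: tuple[int, int, int], mask: np.ndarray, strength: float) -> np.ndarray:
    """Logistic weight decreasing from lung base to apex.

    ``strength`` controls the ramp steepness; 0 gives a flat weight, i.e. no
    systematic apico-basal trend.
    """
    nz = shape[0]
    zs = np.where(mask.any(axis=(1, 2)))[0]
    z_base, z_apex = int(zs.min()), int(zs.max())
    t = (np.arange(nz) - z_base) / max(z_apex - z_base, 1)
    w = 1.0 / (1.0 + np.exp(strength * (t - 0.5)))
    return w[:, None, None] * np.ones(shape)


def _disease_mask(
    rng: np.random.Generator,
    cfg: CohortConfig,
    lungs: np.ndarray,
    fraction: float,
) -> np.ndarray:
    """Threshold a basally weighted correlated field to the target extent."""
    if fraction <= 0:
        return np.zeros(cfg.volume_shape, dtype=bool)
    n_target = fraction * lungs.sum()
    if n_target < 1:
        raise GenerationError(
            f"extent {fraction:.3f} infeasible for a lung of {lungs.sum()} voxels"
        )
    field = _correlated_field(
        rng, cfg.volume_shape, cfg.voxel_spacing, cfg.texture_correlation_length
    )
    weighted = field * _basal_ramp(cfg.volume_shape, lungs, cfg.basal_gradient_strength)
    in_lung = weighted[lungs]
    thresh = np.quantile(in_lung, 1.0 - fraction)
    disease = np.zeros(cfg.volume_shape, dtype=bool)
    disease[lungs] = in_lung > thresh
    return disease


def _draw_fraction(rng: np.random.Generator, cfg: CohortConfig, label: Label) -> float:
    """Per-patient extent, drawn inside the label's band.

    Limited: uniform over [0.4, 1.0] x configured limited extent (stays
    below the 20 % threshold). Extensive: uniform between a point a quarter
    of the way above the threshold and the configured extensive extent.
    """
    if label == "none":
        return 0.0
    if label == "limited":
        return float(rng.uniform(0.4, 1.0) * cfg.disease_extent_limited)
    lo = 0.20 + 0.25 * (cfg.disease_extent_extensive - 0.20)
    return float(rng.uniform(lo, cfg.disease_extent_extensive))


# ---------------------------------------------------------------------------
# Patient assembly
# ---------------------------------------------------------------------------

def _protocol_indices(cfg: CohortConfig, lungs: np.ndarray) -> tuple[list[int], list[int]]:
    """z indices of the lower (6) and upper (3) sub-scan positions."""
    dz = cfg.voxel_spacing[0]
    step = int(round(LOWER_SUBSCAN_SPACING_MM / dz))
    zs = np.where(lungs.any(axis=(1, 2)))[0]
    z_base = int(zs.min())
    lower = [z_base + 1 + k * step for k in range(LOWER_SUBSCAN_POSITIONS)]
    nz = cfg.volume_shape[0]
    # The upper sub-scan is discarded by the analysis; its spacing is not
    # protocol-constrained, so shrink it when the volume is short.
    up_step = min(
        max(int(round(UPPER_SUBSCAN_SPACING_MM / dz)), 1),
        (nz - 1 - lower[-1]) // UPPER_SUBSCAN_POSITIONS,
    )
    upper = [lower[-1] + up_step * (k + 1) for k in range(UPPER_SUBSCAN_POSITIONS)]
    if lower[-1] >= nz or up_step < 1 or upper[-1] >= nz:
        raise GenerationError(
            "volume too short along z for the nine-slice reduced protocol"
        )
    return lower, upper


def _make_patient(
    patient_id: str,
    label: Label,
    cfg: CohortConfig,
    lungs: np.ndarray,
    rng: np.random.Generator,
) -> SyntheticPatient:
    shape, spacing = cfg.volume_shape, cfg.voxel_spacing
    fraction = _draw_fraction(rng, cfg, label)
    disease = _disease_mask(rng, cfg, lungs, fraction)

    healthy_tex = _correlated_field(rng, shape, spacing, cfg.texture_correlation_length)
    disease_tex = _correlated_field(rng, shape, spacing, cfg.texture_correlation_length)
    # Soft disease edge: a one-voxel blur of the indicator blends the HU
    # shift into the surroundings, as fibrotic margins are not step edges.
    soft = ndimage.gaussian_filter(disease.astype(np.float32), sigma=1.0)
    anatomy = (
        cfg.healthy_mean_hu
        + HEALTHY_TEXTURE_SD * healthy_tex
        + (cfg.disease_mean_hu - cfg.healthy_mean_hu) * soft
        + DISEASE_TEXTURE_SD * soft * disease_tex
    ).astype(np.float32)
    anatomy[~lungs & (anatomy < -1000)] = -1000.0

    volume = CTVolume(anatomy, spacing=spacing)

    lower_idx, upper_idx = _protocol_indices(cfg, lungs)
    slices: list[ProtocolSlice] = []
    for tag, idxs in (("lower", lower_idx), ("upper", upper_idx)):
        for zi in idxs:
            sds = [cfg.noise_sd_low, cfg.noise_sd_high]
            if rng.random() < 0.5:       # randomized duplicate order
                sds = sds[::-1]
            plane = anatomy[zi]
            dups = [
                plane + rng.normal(0.0, sd, size=plane.shape).astype(np.float32)
                for sd in sds
            ]
            slices.append(
                ProtocolSlice(
                    position=float(volume.slice_positions[zi]),
                    sub_scan=tag,
                    duplicates=dups,
                    mask=lungs[zi],
                )
            )
    protocol = SliceProtocol(slices=slices, pixel_spacing=(spacing[1], spacing[2]))

    return SyntheticPatient(
        patient_id=patient_id,
        label=label,
        fc_volume=volume,
        fc_mask=ROIMask(lungs),
        fc_disease_mask=disease,
        sr_stack=protocol,
        true_disease_fraction=fraction,
    )


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Generate the full cohort: deterministic given (config, seed)."""
    lungs = lung_mask(config.volume_shape)
    if not lungs.any():
        raise GenerationError("lung mask is empty for this volume shape")
    rng = np.random.default_rng(config.seed)
    patients: list[SyntheticPatient] = []
    counts = {"none": config.n_none, "limited": config.n_limited,
              "extensive": config.n_extensive}
    i = 0
    for label in LABELS:
        for _ in range(counts[label]):
            patients.append(
                _make_patient(f"P{i:03d}", label, config, lungs, rng)  # type: ignore[arg-type]
            )
            i += 1
    return patients


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def disease_fraction(patient: SyntheticPatient) -> float:
    """Fraction of lung-mask voxels carrying disease."""
    n_lung = patient.fc_mask.n_voxels
    if n_lung == 0:
        raise GenerationError("empty lung mask")
    n_dis = int((patient.fc_disease_mask & patient.fc_mask.mask).sum())
    return n_dis / n_lung


def basal_profile(patient: SyntheticPatient) -> np.ndarray:
    """Per-slice disease fraction along z, base (index 0) to apex.

    Slices without lung voxels contribute 0. Used to verify that disease
    concentrates basally when the gradient strength is positive.
    """
    lung_per_slice = patient.fc_mask.mask.sum(axis=(1, 2)).astype(float)
    dis_per_slice = (patient.fc_disease_mask & patient.fc_mask.mask).sum(axis=(1, 2))
    out = np.zeros_like(lung_per_slice)
    nonzero = lung_per_slice > 0
    out[nonzero] = dis_per_slice[nonzero] / lung_per_slice[nonzero]
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_cohort(patients: list[SyntheticPatient], config: CohortConfig,
                 out_dir: str | Path) -> Path:
    """Write NIfTI volumes/masks, the sr stacks, a manifest CSV and config JSON."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in patients:
        # NIfTI stores (x, y, z); transpose from our (z, y, x) convention.
        sp = p.fc_volume.spacing
        affine = np.diag([sp[2], sp[1], sp[0], 1.0])
        vol_path = out / f"{p.patient_id}_ct.nii.gz"
        mask_path = out / f"{p.patient_id}_lungmask.nii.gz"
        nib.save(nib.Nifti1Image(p.fc_volume.intensities.T, affine), vol_path)
        nib.save(
            nib.Nifti1Image(p.fc_mask.mask.T.astype(np.uint8), affine), mask_path
        )
        sr_path = out / f"{p.patient_id}_srstack.nii.gz"
        planes = []
        meta = []
        for s in p.sr_stack.slices:
            for di, d in enumerate(s.duplicates):
                planes.append(d)
                meta.append(
                    {"position": s.position, "sub_scan": s.sub_scan, "duplicate": di}
                )
        psp = p.sr_stack.pixel_spacing
        sr_affine = np.diag([psp[1], psp[0], 1.0, 1.0])
        nib.save(nib.Nifti1Image(np.stack(planes, axis=-1).transpose(1, 0, 2), sr_affine), sr_path)
        (out / f"{p.patient_id}_srstack.json").write_text(
            json.dumps({"pixel_spacing": list(psp), "planes": meta}, indent=1)
        )
        rows.append(
            {
                "patient_id": p.patient_id,
                "label": p.label,
                "true_disease_fraction": p.true_disease_fraction,
                "ct_path": vol_path.name,
                "mask_path": mask_path.name,
                "sr_path": sr_path.name,
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    (out / "cohort_config.json").write_text(config.model_dump_json(indent=1))
    return out


def cohort_labels(patients: list[SyntheticPatient]) -> pd.Series:
    return pd.Series(
        [p.label for p in patients], index=[p.patient_id for p in patients],
        name="label",
    )
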