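"""Seeded synthetic diffusion-MRI cohort generator.

The clinical dataset behind this analysis is not publicly deposited, so every
downstream stage is exercised on synthetic patients whose statistical
structure matches what the analysis assumes:

* a four-b-value direction-averaged DWI series per patient (b = 0, 500, 1000,
  2000 s/mm^2 with 2/6/6/12 directions), simulated from the four-compartment
  decay model with Rician (magnitude) noise averaged over directions;
* prostate / peripheral-zone / central-gland segmentations (the two zones
  partition the gland), a single ellipsoidal lesion for every patient with
  grade group >= 1, and an optional inflammation focus in benign/low-grade
  patients that emulates the classic ADC confounder (benign tissue with low
  apparent diffusion but little truly restricted signal);
* a cohort table with histopathology grade group, radiologist PI-RADS
  category, and lesion zone, calibrated so that per-category csPCa detection
  rates, grade-group marginals, and zone subgroup compositions match the
  published clinical cohort this generator emulates.

Tissue archetype fractions are simulator parameters, not clinical claims;
they are chosen so tumor voxels have a high restricted fraction (scaling with
grade group) while inflammation has low mono-exponential ADC but a small
restricted fraction, and so that the dim periprostatic tissue inside the 5-mm
search margin makes the ratio-based min-ADC statistic noise-dominated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .model import N_COMPARTMENTS, design_matrix, forward_signal
from .reduction import SegmentationSet
from .rsi import DwiSeries

__all__ = [
    "AcquisitionProtocol",
    "TissueArchetype",
    "DetectionModel",
    "ZoneModel",
    "CohortConfig",
    "SyntheticPatient",
    "CohortResult",
    "simulate_voxel_signal",
    "sample_pirads",
    "simulate_cohort",
    "CLINICAL_PIRADS_COUNTS",
    "CLINICAL_GRADE_GROUP_COUNTS",
    "CLINICAL_ZONE_COUNTS",
    "default_detection_model",
]

# ---------------------------------------------------------------------------
# Calibration constants from the published clinical cohort (n = 151).
# ---------------------------------------------------------------------------

#: Per-PI-RADS-category patient counts (negative = benign or grade group 1,
#: positive = csPCa).  Category 5: 54/64 positive, a detection rate of 84.4%.
CLINICAL_PIRADS_COUNTS: dict[int, tuple[int, int]] = {
    1: (0, 0),
    2: (2, 3),
    3: (23, 4),
    4: (30, 25),
    5: (10, 54),
}

#: Histopathology grade-group counts (benign, GG1..GG5).
CLINICAL_GRADE_GROUP_COUNTS: tuple[int, ...] = (25, 40, 38, 20, 16, 12)

#: Zone subgroup compositions (benign, grade group 1, csPCa) for patients
#: whose lesion lay only in the peripheral or only in the transition zone.
CLINICAL_ZONE_COUNTS: dict[str, tuple[int, int, int]] = {
    "peripheral": (15, 23, 65),
    "transition": (14, 15, 8),
}


class AcquisitionProtocol(BaseModel):
    """Diffusion acquisition: b-values with their direction counts."""

    b_values: tuple[float, ...] = (0.0, 500.0, 1000.0, 2000.0)
    directions_per_b: tuple[int, ...] = (2, 6, 6, 12)
    echo_time: float = 68.0  # ms, metadata only
    repetition_time: float = 4500.0  # ms, metadata only

    @model_validator(mode="after")
    def _check(self) -> "AcquisitionProtocol":
        b = self.b_values
        if len(b) == 0 or b[0] != 0.0:
            raise ValueError("first b-value must be 0")
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError("b_values must be strictly increasing")
        if len(self.directions_per_b) != len(b):
            raise ValueError("directions_per_b must match b_values in length")
        if any(d < 1 for d in self.directions_per_b):
            raise ValueError("each b-value needs at least one direction")
        return self


class TissueArchetype(BaseModel):
    """Compartment-fraction template for one tissue class."""

    name: str
    fractions: tuple[float, float, float, float]
    fraction_dispersion: float = Field(0.0, ge=0)

    @field_validator("fractions")
    @classmethod
    def _nonneg(cls, v):
        if any(f < 0 for f in v):
            raise ValueError("archetype fractions must be nonnegative")
        if sum(v) > 1.5:
            raise ValueError("archetype fractions sum above 1.5 (normalized units)")
        return v


def _default_archetypes() -> dict[str, TissueArchetype]:
    return {
        # peripheral-zone background: watery, high free fraction, high ADC
        "stroma": TissueArchetype(
            name="stroma", fractions=(0.04, 0.48, 0.38, 0.10), fraction_dispersion=0.03
        ),
        # central-gland background: denser glandular tissue, slightly lower ADC
        "benign_epithelium": TissueArchetype(
            name="benign_epithelium",
            fractions=(0.06, 0.58, 0.26, 0.10),
            fraction_dispersion=0.03,
        ),
        # tumor: high restricted fraction (C1 scaled further by grade group)
        "tumor": TissueArchetype(
            name="tumor", fractions=(0.30, 0.45, 0.15, 0.10), fraction_dispersion=0.04
        ),
        # inflammation: hindered-dominated, low ADC but low restricted fraction
        "inflammation": TissueArchetype(
            name="inflammation",
            fractions=(0.12, 0.80, 0.05, 0.03),
            fraction_dispersion=0.03,
        ),
        # dim fat-suppressed periprostatic tissue inside the search margin
        "periprostatic": TissueArchetype(
            name="periprostatic",
            fractions=(0.02, 0.05, 0.05, 0.03),
            fraction_dispersion=0.02,
        ),
    }


def default_detection_model() -> "DetectionModel":
    """PI-RADS class-conditionals calibrated to the clinical detection table."""
    neg = np.array([CLINICAL_PIRADS_COUNTS[k][0] for k in range(1, 6)], dtype=float)
    pos = np.array([CLINICAL_PIRADS_COUNTS[k][1] for k in range(1, 6)], dtype=float)
    return DetectionModel(
        p_pirads_pos=tuple(pos / pos.sum()), p_pirads_neg=tuple(neg / neg.sum())
    )


class DetectionModel(BaseModel):
    """P(PI-RADS category | csPCa status), categories 1..5."""

    p_pirads_pos: tuple[float, float, float, float, float]
    p_pirads_neg: tuple[float, float, float, float, float]

    @field_validator("p_pirads_pos", "p_pirads_neg")
    @classmethod
    def _prob(cls, v):
        if any(p < 0 for p in v) or abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("probability vector must be nonnegative and sum to 1")
        return v


class ZoneModel(BaseModel):
    """P(lesion in peripheral zone | csPCa status); remainder is transition."""

    p_peripheral_pos: float = Field(65 / 73, ge=0, le=1)
    p_peripheral_neg: float = Field(38 / 67, ge=0, le=1)


class CohortConfig(BaseModel):
    """Everything that defines a simulated cohort; fully seeded."""

    n_patients: int = Field(151, ge=0)
    grade_group_probs: tuple[float, float, float, float, float, float] = tuple(
        c / sum(CLINICAL_GRADE_GROUP_COUNTS) for c in CLINICAL_GRADE_GROUP_COUNTS
    )
    pirads_given_cspca: DetectionModel = Field(default_factory=default_detection_model)
    lesion_zone_probs: ZoneModel = Field(default_factory=ZoneModel)
    noise_sigma: float = Field(0.05, ge=0)  # b=0 SNR ~ 20 in normalized units
    voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 6.0)
    grid_shape: tuple[int, int, int] = (24, 24, 12)
    seed: int = 0
    protocol: AcquisitionProtocol = Field(default_factory=AcquisitionProtocol)
    archetypes: dict[str, TissueArchetype] = Field(default_factory=_default_archetypes)
    #: fraction of benign/grade-group-1 patients given an inflammation focus
    inflammation_prob: float = Field(0.4, ge=0, le=1)
    #: multiplicative C1 scaling of the tumor archetype by grade group
    grade_c1_scale: dict[int, float] = Field(
        default_factory=lambda: {1: 0.6, 2: 0.85, 3: 1.0, 4: 1.1, 5: 1.2}
    )
    prostate_radii_mm: tuple[float, float, float] = (20.0, 16.0, 13.0)
    central_radii_mm: tuple[float, float, float] = (11.0, 9.0, 9.0)
    lesion_radii_mm: tuple[float, float, float] = (7.0, 7.0, 6.5)
    #: per-patient lognormal-ish spread of lesion/inflammation C1 intensity
    patient_intensity_sd: float = Field(0.12, ge=0)
    #: raw scanner gain range; normalization must undo it
    scanner_gain_range: tuple[float, float] = (200.0, 600.0)

    @field_validator("grade_group_probs")
    @classmethod
    def _prob6(cls, v):
        if any(p < 0 for p in v) or abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("grade_group_probs must be nonnegative and sum to 1")
        return v

    @field_validator("grid_shape")
    @classmethod
    def _grid(cls, v):
        if any(n < 8 for n in v):
            raise ValueError("grid_shape components must be >= 8")
        return v


@dataclass
class SyntheticPatient:
    """One simulated patient: images, masks, and ground truth."""

    patient_id: str
    dwi: DwiSeries
    segmentation: SegmentationSet
    grade_group: int
    lesion_zone: str
    lesion_mask: np.ndarray
    inflammation_mask: np.ndarray
    pirads: int


@dataclass
class CohortResult:
    patients: list[SyntheticPatient]
    table: pd.DataFrame


# ---------------------------------------------------------------------------
# Signal simulation
# ---------------------------------------------------------------------------

def simulate_voxel_signal(
    fractions, protocol: AcquisitionProtocol, noise_sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """One magnitude measurement per b-value for a single voxel.

    The noiseless component is sum_i C_i exp(-b D_i) (flow contributing only
    at b = 0); when ``noise_sigma > 0`` Rician noise is applied independently
    per b-value: output = |noiseless + complex Gaussian(0, sigma per channel)|.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (N_COMPARTMENTS,):
        raise ValueError(f"fractions must be a {N_COMPARTMENTS}-vector")
    if np.any(fractions < 0):
        raise ValueError("compartment fractions must be nonnegative")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    clean = forward_signal(fractions, protocol.b_values)
    if noise_sigma == 0:
        return clean
    re = clean + rng.normal(0.0, noise_sigma, clean.shape)
    im = rng.normal(0.0, noise_sigma, clean.shape)
    return np.hypot(re, im)


def _direction_averaged_volume(
    clean: np.ndarray, protocol: AcquisitionProtocol, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Direction-averaged noisy volumes: per b, the arithmetic mean of
    ``directions_per_b`` independent magnitude measurements."""
    if sigma == 0:
        return clean.copy()
    out = np.empty_like(clean)
    for j, n_dir in enumerate(protocol.directions_per_b):
        a = clean[..., j]
        re = a[None] + rng.normal(0.0, sigma, (n_dir,) + a.shape)
        im = rng.normal(0.0, sigma, (n_dir,) + a.shape)
        out[..., j] = np.hypot(re, im).mean(axis=0)
    return out


def sample_pirads(is_cspca: bool, model: DetectionModel, rng: np.random.Generator) -> int:
    """Draw a PI-RADS category (1-5) from the class-conditional model."""
    p = model.p_pirads_pos if is_cspca else model.p_pirads_neg
    return int(rng.choice(5, p=np.asarray(p))) + 1


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _voxel_centers_mm(grid_shape, voxel_size_mm):
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(grid_shape, voxel_size_mm)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(grid_shape, voxel_size_mm, center_mm, radii_mm) -> np.ndarray:
    xs, ys, zs = _voxel_centers_mm(grid_shape, voxel_size_mm)
    q = (
        ((xs - center_mm[0]) / radii_mm[0]) ** 2
        + ((ys - center_mm[1]) / radii_mm[1]) ** 2
        + ((zs - center_mm[2]) / radii_mm[2]) ** 2
    )
    return q <= 1.0


def _build_segmentation(config: CohortConfig, scale: float) -> SegmentationSet:
    prostate = _ellipsoid(
        config.grid_shape,
        config.voxel_size_mm,
        (0.0, 0.0, 0.0),
        tuple(r * scale for r in config.prostate_radii_mm),
    )
    central = _ellipsoid(
        config.grid_shape,
        config.voxel_size_mm,
        (0.0, 0.0, 0.0),
        tuple(r * scale for r in config.central_radii_mm),
    )
    central &= prostate
    return SegmentationSet(
        prostate=prostate,
        peripheral_zone=prostate & ~central,
        central_gland=central,
        voxel_size_mm=config.voxel_size_mm,
    )


def _place_focus(
    zone_mask: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """An ellipsoidal focus centered on a random zone voxel, clipped to the zone."""
    idx = np.argwhere(zone_mask)
    if idx.size == 0:
        raise ValueError("zone mask is empty; grid too small to place a lesion")
    center_vox = idx[rng.integers(len(idx))]
    center_mm = tuple(
        (c - (n - 1) / 2.0) * s
        for c, n, s in zip(center_vox, config.grid_shape, config.voxel_size_mm)
    )
    focus = _ellipsoid(config.grid_shape, config.voxel_size_mm, center_mm, config.lesion_radii_mm)
    focus &= zone_mask
    if not focus.any():
        raise ValueError("could not place a lesion inside the zone; grid too small")
    return focus


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _patient_fraction_volume(
    config: CohortConfig,
    seg: SegmentationSet,
    lesion_mask: np.ndarray,
    inflammation_mask: np.ndarray,
    grade_group: int,
    rng: np.random.Generator,
) -> np.ndarray:
    arch = config.archetypes
    shape = tuple(config.grid_shape)
    fractions = np.empty(shape + (N_COMPARTMENTS,))
    dispersion = np.empty(shape)

    def paint(mask, archetype: TissueArchetype, frac_override=None):
        fractions[mask] = frac_override if frac_override is not None else archetype.fractions
        dispersion[mask] = archetype.fraction_dispersion

    paint(np.ones(shape, dtype=bool), arch["periprostatic"])
    paint(seg.peripheral_zone, arch["stroma"])
    paint(seg.central_gland, arch["benign_epithelium"])

    intensity = float(
        np.clip(rng.normal(1.0, config.patient_intensity_sd), 0.6, 1.4)
    )
    if inflammation_mask.any():
        f = np.array(arch["inflammation"].fractions)
        c1 = f[0] * intensity
        f = np.array([c1, f[1] + f[0] - c1, f[2], f[3]])
        paint(inflammation_mask, arch["inflammation"], f)
    if lesion_mask.any():
        f = np.array(arch["tumor"].fractions)
        c1 = f[0] * config.grade_c1_scale[grade_group] * intensity
        # C2 absorbs the difference so total b=0 signal stays comparable
        f = np.array([c1, max(f[1] + f[0] - c1, 0.0), f[2], f[3]])
        paint(lesion_mask, arch["tumor"], f)

    fractions += rng.normal(0.0, 1.0, fractions.shape) * dispersion[..., None]
    return np.clip(fractions, 0.0, None)


def simulate_cohort(config: CohortConfig) -> CohortResult:
    """Generate the full synthetic cohort; deterministic given ``config.seed``.

    Every patient with grade group >= 1 carries an ellipsoidal lesion (tumor
    archetype) in the sampled zone; a configurable fraction of benign and
    grade-group-1 patients additionally carries an inflammation focus.
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(max(config.n_patients, 1))
    A_check = design_matrix(config.protocol.b_values)
    if A_check.shape[0] < N_COMPARTMENTS:
        raise ValueError("protocol must provide at least four b-values")

    gg_probs = np.asarray(config.grade_group_probs)
    patients: list[SyntheticPatient] = []
    rows = []
    for i in range(config.n_patients):
        rng = np.random.default_rng(streams[i])
        pid = f"P{i:04d}"
        grade_group = int(rng.choice(6, p=gg_probs))
        cspca = grade_group >= 2
        zp = (
            config.lesion_zone_probs.p_peripheral_pos
            if cspca
            else config.lesion_zone_probs.p_peripheral_neg
        )
        zone = "peripheral" if rng.random() < zp else "transition"
        pirads = sample_pirads(cspca, config.pirads_given_cspca, rng)

        seg = _build_segmentation(config, scale=float(rng.uniform(0.92, 1.08)))
        zone_mask = seg.peripheral_zone if zone == "peripheral" else seg.central_gland

        lesion_mask = np.zeros(tuple(config.grid_shape), dtype=bool)
        if grade_group >= 1:
            lesion_mask = _place_focus(zone_mask, config, rng)
        inflammation_mask = np.zeros_like(lesion_mask)
        if grade_group <= 1 and rng.random() < config.inflammation_prob:
            inflammation_mask = _place_focus(zone_mask, config, rng) & ~lesion_mask

        fractions = _patient_fraction_volume(
            config, seg, lesion_mask, inflammation_mask, grade_group, rng
        )
        clean = fractions @ design_matrix(config.protocol.b_values).T
        noisy = _direction_averaged_volume(clean, config.protocol, config.noise_sigma, rng)
        gain = float(rng.uniform(*config.scanner_gain_range))
        dwi = DwiSeries(
            signal=noisy * gain,
            b_values=config.protocol.b_values,
            voxel_size_mm=config.voxel_size_mm,
            normalized=False,
        )
        patients.append(
            SyntheticPatient(
                patient_id=pid,
                dwi=dwi,
                segmentation=seg,
                grade_group=grade_group,
                lesion_zone=zone,
                lesion_mask=lesion_mask,
                inflammation_mask=inflammation_mask,
                pirads=pirads,
            )
        )
        rows.append(
            {
                "patient_id": pid,
                "grade_group": grade_group,
                "pirads": pirads,
                "lesion_zone": zone,
                "seed": config.seed,
            }
        )

    table = pd.DataFrame(
        rows, columns=["patient_id", "grade_group", "pirads", "lesion_zone", "seed"]
    )
    return CohortResult(patients=patients, table=table)
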