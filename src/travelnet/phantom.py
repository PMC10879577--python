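"""Synthetic 3D volumes with controllable class signal and center nuisance.

Real preprocessed T1-weighted MRI cannot be redistributed, so training runs
on phantoms: an ellipsoidal "brain" of baseline tissue intensity containing
a designated atrophy region whose intensity is reduced for disease-positive
participants.  On top of that class signal the generator layers the
heterogeneity axes of a real multi-center study — a per-center multiplicative
gain, a smooth multiplicative bias field (per center), an age-related
regional intensity drift, and vendor-dependent additive Gaussian noise.
Every volume is a pure function of (master_seed, participant_id), so no
image files ever need to exist on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from ._seeds import derive_seed
from .cohort import Cohort, ParticipantRecord, VENDORS

__all__ = [
    "PhantomSpec",
    "VolumeSample",
    "CenterEffects",
    "make_template",
    "center_effect_params",
    "render_participant",
    "zscore_volume",
    "PhantomVolumes",
    "NiftiVolumes",
    "save_nifti",
    "load_nifti",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Generator parameters; all effects are off when their spread/size is 0.

    Attributes
    ----------
    grid_size
        Voxels per axis (cubic volume); minimum 8.
    class_effect_size
        Fractional intensity reduction of the atrophy region for label-1
        participants (0.15 means a 15% darker region).
    age_effect_slope
        Additional fractional intensity change of the atrophy region per
        decade of age relative to age 60 (negative = darker with age).
    center_gain_sd
        SD of the per-center multiplicative gain, drawn around 1.
    bias_field_amplitude
        Scale of the per-center smooth multiplicative bias field (exponent
        of a first-order polynomial in normalised coordinates).
    noise_sd_by_vendor
        Additive white Gaussian noise SD per scanner vendor.
    master_seed
        Root of every per-participant and per-center random stream.
    """

    grid_size: int = 24
    class_effect_size: float = 0.15
    age_effect_slope: float = -0.01
    center_gain_sd: float = 0.10
    bias_field_amplitude: float = 0.10
    noise_sd_by_vendor: Mapping[str, float] = field(
        default_factory=lambda: {"Siemens": 0.05, "GE": 0.06, "Philips": 0.07}
    )
    master_seed: int = 0

    def validate(self) -> None:
        if self.grid_size < 8:
            raise ValueError(f"grid_size must be >= 8, got {self.grid_size}")
        if self.class_effect_size < 0:
            raise ValueError("class_effect_size must be >= 0")
        if self.center_gain_sd < 0 or self.bias_field_amplitude < 0:
            raise ValueError("spreads must be >= 0")
        for v, sd in self.noise_sd_by_vendor.items():
            if v not in VENDORS:
                raise ValueError(f"unknown vendor {v!r}")
            if sd < 0:
                raise ValueError("noise sd must be >= 0")


@dataclass(frozen=True)
class VolumeSample:
    """A rendered 3D intensity array together with its participant record."""

    intensities: np.ndarray
    record: ParticipantRecord


@dataclass(frozen=True)
class CenterEffects:
    """Per-center nuisance parameters: gain and bias-field coefficients."""

    gain: float
    bias_coeffs: np.ndarray  # (3,) linear coefficients over normalised x, y, z


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

# Ellipsoid semi-axes and atrophy-region radius as fractions of the grid.
_SEMI_AXES = (0.42, 0.36, 0.30)
_REGION_RADIUS = 0.12
_REGION_CENTER = (0.0, 0.1, -0.05)  # offset in normalised coordinates


def _normalised_coords(grid_size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ax = (np.arange(grid_size) - (grid_size - 1) / 2.0) / (grid_size / 2.0)
    return np.meshgrid(ax, ax, ax, indexing="ij")


def make_template(grid_size: int = 24) -> tuple[np.ndarray, np.ndarray]:
    """Ellipsoidal tissue template and its interior class-effect region mask.

    Returns ``(template, region_mask)``: the template is 1 inside the
    ellipsoid and 0 outside; the region mask marks a small sphere strictly
    inside the ellipsoid whose intensity carries the disease signal.
    """
    if grid_size < 8:
        raise ValueError(f"grid_size must be >= 8, got {grid_size}")
    x, y, z = _normalised_coords(grid_size)
    a, b, c = _SEMI_AXES
    tissue = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    cx, cy, cz = _REGION_CENTER
    region = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= _REGION_RADIUS**2
    region &= tissue
    return tissue.astype(np.float64), region


def template_tissue_fraction_expected() -> float:
    """Analytic ellipsoid volume fraction of the unit cube (4/3 pi abc / 8)."""
    a, b, c = _SEMI_AXES
    return (4.0 / 3.0) * np.pi * a * b * c / 8.0


# ---------------------------------------------------------------------------
# effects
# ---------------------------------------------------------------------------


def center_effect_params(center_id: str, spec: PhantomSpec) -> CenterEffects:
    """Draw the per-center gain and bias-field coefficients.

    Deterministic per (master_seed, center_id); independent streams per
    center.  The gain is N(1, center_gain_sd); the three bias coefficients
    are N(0, amplitude/2) each, giving a field exp(b . r) with |b . r| of the
    order of the amplitude across the volume.
    """
    rng = np.random.Generator(
        np.random.PCG64(derive_seed(spec.master_seed, "center-fx", center_id))
    )
    gain = 1.0 + spec.center_gain_sd * rng.standard_normal()
    bias = (spec.bias_field_amplitude / 2.0) * rng.standard_normal(3)
    return CenterEffects(gain=float(gain), bias_coeffs=bias)


def _bias_field(grid_size: int, coeffs: np.ndarray) -> np.ndarray:
    x, y, z = _normalised_coords(grid_size)
    return np.exp(coeffs[0] * x + coeffs[1] * y + coeffs[2] * z)


def render_participant(
    record: ParticipantRecord,
    template: np.ndarray,
    region: np.ndarray,
    spec: PhantomSpec,
    effects: CenterEffects | None = None,
) -> VolumeSample:
    """Render one participant's volume from their record.

    Pipeline: start from the tissue template; scale the atrophy region by
    ``1 - class_effect_size`` for label-1 participants and by the age drift
    ``1 + slope * (age - 60)/10``; multiply by the center gain and bias
    field; add vendor noise.  Deterministic given (master_seed,
    participant_id).
    """
    spec.validate()
    if record.vendor not in spec.noise_sd_by_vendor:
        raise ValueError(f"no noise level configured for vendor {record.vendor!r}")
    if effects is None:
        effects = center_effect_params(record.center_id, spec)

    vol = template.copy()
    region_scale = 1.0 + spec.age_effect_slope * (record.age_years - 60.0) / 10.0
    if record.label == 1:
        region_scale *= 1.0 - spec.class_effect_size
    vol[region] *= region_scale

    vol *= effects.gain
    if spec.bias_field_amplitude > 0:
        vol *= _bias_field(template.shape[0], effects.bias_coeffs)

    sd = spec.noise_sd_by_vendor[record.vendor]
    if sd > 0:
        rng = np.random.Generator(
            np.random.PCG64(derive_seed(spec.master_seed, "phantom", record.participant_id))
        )
        vol = vol + sd * rng.standard_normal(vol.shape)
    return VolumeSample(intensities=vol, record=record)


def zscore_volume(vol: np.ndarray) -> np.ndarray:
    """Per-volume z-scoring (the network's input normalisation)."""
    mu = float(vol.mean())
    sd = float(vol.std())
    if sd == 0.0:
        return np.zeros_like(vol, dtype=np.float32)
    return ((vol - mu) / sd).astype(np.float32)


# ---------------------------------------------------------------------------
# volume providers
# ---------------------------------------------------------------------------


class PhantomVolumes:
    """On-the-fly volume provider for a cohort, with an in-memory cache.

    ``get(participant_id)`` returns the z-scored float32 volume the network
    consumes.  Rendering is lazy and cached; the cache for a 24^3 grid costs
    ~55 KB per volume.
    """

    def __init__(self, cohort: Cohort, spec: PhantomSpec):
        spec.validate()
        self.spec = spec
        self._records = {r.participant_id: r for r in cohort.records}
        self._template, self._region = make_template(spec.grid_size)
        self._center_fx: dict[str, CenterEffects] = {}
        self._cache: dict[str, np.ndarray] = {}

    @property
    def grid_size(self) -> int:
        return self.spec.grid_size

    def get(self, participant_id: str) -> np.ndarray:
        if participant_id not in self._cache:
            record = self._records[participant_id]
            fx = self._center_fx.get(record.center_id)
            if fx is None:
                fx = center_effect_params(record.center_id, self.spec)
                self._center_fx[record.center_id] = fx
            sample = render_participant(record, self._template, self._region, self.spec, fx)
            self._cache[participant_id] = zscore_volume(sample.intensities)
        return self._cache[participant_id]

    def get_batch(self, participant_ids: list[str]) -> np.ndarray:
        return np.stack([self.get(pid) for pid in participant_ids])


class NiftiVolumes:
    """Volume provider backed by a directory of NIfTI files.

    Files are looked up as ``{participant_id}.nii.gz`` (or ``.nii``); each
    volume is z-scored on load.  This is the real-data mode: the training
    loops only ever see the provider interface.
    """

    def __init__(self, directory: str | Path, grid_size: int):
        self.directory = Path(directory)
        self.grid_size = grid_size
        self._cache: dict[str, np.ndarray] = {}

    def get(self, participant_id: str) -> np.ndarray:
        if participant_id not in self._cache:
            vol = load_nifti(self._find(participant_id))
            if vol.shape != (self.grid_size,) * 3:
                raise ValueError(
                    f"{participant_id}: expected shape {(self.grid_size,) * 3}, got {vol.shape}"
                )
            self._cache[participant_id] = zscore_volume(vol)
        return self._cache[participant_id]

    def get_batch(self, participant_ids: list[str]) -> np.ndarray:
        return np.stack([self.get(pid) for pid in participant_ids])

    def _find(self, participant_id: str) -> Path:
        for suffix in (".nii.gz", ".nii"):
            p = self.directory / f"{participant_id}{suffix}"
            if p.exists():
                return p
        raise FileNotFoundError(f"no NIfTI volume for {participant_id!r} in {self.directory}")


def save_nifti(vol: np.ndarray, path: str | Path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine=np.eye(4)), str(path))


def load_nifti(path: str | Path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
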