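"""Synthetic cohort generation and dynamic image-series rendering.

Emulates the study design: four groups of rats (PD model, Madopar-treated PD,
sham, control), each animal receiving a substantia-nigra bolus of Gd-DTPA and
a series of post-injection T1-weighted volumes.  Per-animal kinetic parameters
are drawn around the published group means/SDs; the image model is a linear
enhancement map of the analytic concentration field plus additive Gaussian
noise.  MR pulse-sequence physics is out of scope — signal is
baseline + beta·C + noise in arbitrary units.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .forward_model import (
    DEFAULT_ALPHA,
    DOSE_MOL,
    SN_INJECTION_SITE_MM,
    TracerKineticParams,
    ValidationError,
    concentration,
)

__all__ = [
    "GROUP_LABELS",
    "GROUP_PARAM_TABLE",
    "DEFAULT_N_PER_GROUP",
    "GroupSpec",
    "GridSpec",
    "ImageSeries",
    "AnimalRecord",
    "default_cohort_specs",
    "default_times",
    "draw_cohort",
    "render_image_series",
    "ellipsoid_brain_mask",
    "save_image_series",
    "load_image_series",
    "cohort_to_frame",
    "animal_seed",
]

GROUP_LABELS = ("PD", "Madopar", "sham", "control")

# Published per-group (mean, sd): D* and k' in base units (mm²/s and 1/s,
# printed magnitudes are ×10⁻⁴), Vd-max% in percent, t_1/2 in seconds
# (printed in minutes).
GROUP_PARAM_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "PD": {
        "d_eff": (2.744e-4, 0.341e-4),
        "k_clear": (2.153e-4, 0.610e-4),
        "vd_max_pct": (2.392, 0.185),
        "t_half_s": (97.839 * 60.0, 11.874 * 60.0),
    },
    "Madopar": {
        "d_eff": (2.340e-4, 0.448e-4),
        "k_clear": (1.109e-4, 0.333e-4),
        "vd_max_pct": (2.153, 0.102),
        "t_half_s": (84.084 * 60.0, 8.157 * 60.0),
    },
    "sham": {
        "d_eff": (2.078e-4, 0.326e-4),
        "k_clear": (0.879e-4, 0.262e-4),
        "vd_max_pct": (2.091, 0.110),
        "t_half_s": (67.374 * 60.0, 7.222 * 60.0),
    },
    "control": {
        "d_eff": (2.023e-4, 0.501e-4),
        "k_clear": (0.854e-4, 0.355e-4),
        "vd_max_pct": (2.054, 0.090),
        "t_half_s": (69.649 * 60.0, 7.017 * 60.0),
    },
}

#: Animals per group. Ten were enrolled per group, but behavioural screening
#: implies attrition; n = 9 is the unique equal n in {5..10} jointly consistent
#: with all four published F statistics (see stats.audit_equal_n).
DEFAULT_N_PER_GROUP = 9

_MECHANISTIC_PARAMS = ("d_eff", "k_clear")
_EMPIRICAL_PARAMS = ("d_eff", "k_clear", "vd_max_pct", "t_half_s")


@dataclass(frozen=True)
class GroupSpec:
    """Population description of one study group.

    ``mode`` selects what is drawn per animal: ``mechanistic`` draws the
    kinetic parameters (d_eff, k_clear) only, leaving Vd-max% and t_1/2 to the
    estimation pipeline; ``empirical`` draws all four observables directly so
    the group-statistics stage can be exercised in isolation.
    """

    label: str
    n: int
    param_means: dict[str, float]
    param_sds: dict[str, float]
    mode: str = "mechanistic"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"group {self.label!r}: n must be >= 2, got {self.n}")
        if self.mode not in ("mechanistic", "empirical"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        needed = _MECHANISTIC_PARAMS if self.mode == "mechanistic" else _EMPIRICAL_PARAMS
        for p in needed:
            if p not in self.param_means or p not in self.param_sds:
                raise ValidationError(f"group {self.label!r}: missing mean/sd for {p!r}")
        for p, sd in self.param_sds.items():
            if sd < 0:
                raise ValidationError(f"group {self.label!r}: sd for {p!r} must be >= 0")


def default_cohort_specs(
    mode: str = "mechanistic",
    n_per_group: int = DEFAULT_N_PER_GROUP,
    labels: tuple[str, ...] = GROUP_LABELS,
) -> list[GroupSpec]:
    """Group specs with the published means/SDs for the four study groups."""
    specs = []
    keys = _MECHANISTIC_PARAMS if mode == "mechanistic" else _EMPIRICAL_PARAMS
    for label in labels:
        table = GROUP_PARAM_TABLE[label]
        specs.append(
            GroupSpec(
                label=label,
                n=n_per_group,
                param_means={k: table[k][0] for k in keys},
                param_sds={k: table[k][1] for k in keys},
                mode=mode,
            )
        )
    return specs


def default_times(n_volumes: int = 12, start_s: float = 600.0, step_s: float = 900.0) -> np.ndarray:
    """Default acquisition grid: 12 volumes 15 min apart, first 10 min post-injection."""
    return start_s + step_s * np.arange(n_volumes)


# ---------------------------------------------------------------------------
# Animal records
# ---------------------------------------------------------------------------


@dataclass
class AnimalRecord:
    """One animal: group membership, ground truth (synthetic) and estimates.

    In mechanistic mode the observable fields (``d_eff`` … ``t_half_s``) start
    as NaN and are filled by the estimation stage; in empirical mode they are
    drawn directly from the group distributions.
    """

    animal_id: str
    group: str
    mode: str
    seed: int
    true_d_eff: float = float("nan")
    true_k_clear: float = float("nan")
    d_eff: float = float("nan")
    k_clear: float = float("nan")
    vd_max_pct: float = float("nan")
    t_half_s: float = float("nan")
    dose_eff: float = float("nan")
    converged: bool = False
    diagnostics: dict = field(default_factory=dict)

    def true_params(
        self,
        dose: float = DOSE_MOL,
        alpha: float = DEFAULT_ALPHA,
        center: tuple[float, float, float] = SN_INJECTION_SITE_MM,
    ) -> TracerKineticParams:
        if not (np.isfinite(self.true_d_eff) and np.isfinite(self.true_k_clear)):
            raise ValidationError(f"animal {self.animal_id}: no mechanistic ground truth")
        return TracerKineticParams(
            d_eff=self.true_d_eff, k_clear=self.true_k_clear,
            dose=dose, alpha=alpha, center=center,
        )


def animal_seed(master_seed: int, group_label: str, index: int) -> int:
    """Deterministic per-animal sub-seed, stable under group reordering.

    Mixes the master seed with a CRC of the group label and the within-group
    index, so adding or reordering groups in a config never perturbs the
    draws of the others.
    """
    h = zlib.crc32(f"{group_label}:{index}".encode())
    return int((master_seed * 2654435761 + h) % (2**31 - 1))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated at zero by rejection (negligible mass removed here)."""
    if sd == 0:
        return float(mean)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0:
            return float(x)
    raise ValidationError(f"truncated normal rejection failed for mean={mean}, sd={sd}")


def draw_cohort(specs: list[GroupSpec], seed: int) -> list[AnimalRecord]:
    """Draw per-animal parameters for every group.

    Parameters are independent normals with each group's means/SDs, truncated at
    zero.  Reproducible: the same ``seed`` yields the same cohort, per animal,
    regardless of group order in ``specs``.
    """
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValidationError("group labels must be unique within a cohort")
    records: list[AnimalRecord] = []
    for spec in specs:
        for i in range(spec.n):
            sub_seed = animal_seed(seed, spec.label, i)
            rng = np.random.default_rng(sub_seed)
            rec = AnimalRecord(
                animal_id=f"{spec.label}_{i + 1:02d}",
                group=spec.label,
                mode=spec.mode,
                seed=sub_seed,
            )
            if spec.mode == "mechanistic":
                rec.true_d_eff = _truncated_normal(rng, spec.param_means["d_eff"], spec.param_sds["d_eff"])
                rec.true_k_clear = _truncated_normal(rng, spec.param_means["k_clear"], spec.param_sds["k_clear"])
            else:
                for name in _EMPIRICAL_PARAMS:
                    setattr(
                        rec, name,
                        _truncated_normal(rng, spec.param_means[name], spec.param_sds[name]),
                    )
            records.append(rec)
    return records


def cohort_to_frame(records: list[AnimalRecord]) -> pd.DataFrame:
    """Cohort table with columns animal_id, group, mode, true_d_eff, true_k_clear, seed."""
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "group": [r.group for r in records],
            "mode": [r.mode for r in records],
            "true_d_eff": [r.true_d_eff for r in records],
            "true_k_clear": [r.true_k_clear for r in records],
            "seed": [r.seed for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Isotropic voxel grid: shape, voxel size (mm) and world origin of voxel (0,0,0)."""

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 0.2
    origin: tuple[float, float, float] | None = None  # None: centre grid on the SN site

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValidationError("voxel_size must be > 0")
        if len(self.shape) != 3 or any(s < 2 for s in self.shape):
            raise ValidationError("shape must be three dims, each >= 2")

    def resolved_origin(self, center: tuple[float, float, float]) -> np.ndarray:
        """Origin placing ``center`` at the grid's geometric centre when unset."""
        if self.origin is not None:
            return np.asarray(self.origin, dtype=float)
        half = (np.asarray(self.shape) - 1) / 2.0 * self.voxel_size
        return np.asarray(center, dtype=float) - half

    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * self.voxel_size


@dataclass
class ImageSeries:
    """A time-stamped stack of 3-D signal volumes on a metric voxel grid.

    ``volumes`` has shape (nx, ny, nz, nt) with time last, matching the NIfTI
    4-D layout.  ``brain_mask`` is a boolean volume whose voxel count defines
    the reference brain volume for Vd-max% denominators.
    """

    volumes: np.ndarray
    times: np.ndarray
    voxel_size: float
    origin: np.ndarray
    brain_mask: np.ndarray
    noise_sd: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.volumes.ndim != 4:
            raise ValidationError("volumes must be 4-D (x, y, z, t)")
        if self.volumes.shape[:3] != self.brain_mask.shape:
            raise ValidationError("volumes and brain_mask must share one grid shape")
        if self.volumes.shape[3] != self.times.size:
            raise ValidationError("number of volumes must match number of times")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if self.voxel_size <= 0:
            raise ValidationError("voxel_size must be > 0")

    @property
    def voxel_volume(self) -> float:
        return self.voxel_size**3

    @property
    def mask_volume(self) -> float:
        """Reference brain volume, mm³ (voxel count × voxel volume)."""
        return float(self.brain_mask.sum()) * self.voxel_volume

    def voxel_distances(self, center) -> np.ndarray:
        """Distance of every voxel centre from a world-space point, mm."""
        nx, ny, nz = self.volumes.shape[:3]
        cx, cy, cz = np.asarray(center, dtype=float) - self.origin
        x = np.arange(nx) * self.voxel_size - cx
        y = np.arange(ny) * self.voxel_size - cy
        z = np.arange(nz) * self.voxel_size - cz
        return np.sqrt(
            x[:, None, None] ** 2 + y[None, :, None] ** 2 + z[None, None, :] ** 2
        )


def ellipsoid_brain_mask(shape: tuple[int, int, int], semi_axis_fraction: float = 0.45) -> np.ndarray:
    """Ellipsoid mask centred in the grid with semi-axes a fraction of each extent."""
    idx = [np.arange(n) - (n - 1) / 2.0 for n in shape]
    semi = [semi_axis_fraction * n for n in shape]
    u = (
        (idx[0][:, None, None] / semi[0]) ** 2
        + (idx[1][None, :, None] / semi[1]) ** 2
        + (idx[2][None, None, :] / semi[2]) ** 2
    )
    return u <= 1.0


def render_image_series(
    params: TracerKineticParams,
    grid: GridSpec,
    times,
    beta: float,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> ImageSeries:
    """Render a synthetic dynamic series: baseline + beta·C + Gaussian noise.

    ``beta`` is the linear signal-per-concentration factor (arbitrary signal
    units per mol/mm³); noise is i.i.d. per voxel and time point.  The
    injection centre must fall inside the grid.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0):
        raise ValidationError("times must all be > 0")
    if np.any(np.diff(times) <= 0):
        raise ValidationError("times must be strictly increasing")
    if beta <= 0:
        raise ValidationError("beta must be > 0")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")

    origin = grid.resolved_origin(params.center)
    rel = (np.asarray(params.center) - origin) / grid.voxel_size
    if np.any(rel < 0) or np.any(rel > np.asarray(grid.shape) - 1):
        raise ValidationError(
            f"injection center {tuple(params.center)} lies outside the voxel grid"
        )

    mask = ellipsoid_brain_mask(grid.shape)
    dummy = ImageSeries(
        volumes=np.zeros(grid.shape + (times.size,)),
        times=times, voxel_size=grid.voxel_size, origin=origin,
        brain_mask=mask, noise_sd=noise_sd,
    )
    r = dummy.voxel_distances(params.center)
    vols = np.empty(grid.shape + (times.size,))
    for k, t in enumerate(times):
        vols[..., k] = baseline + beta * concentration(params, r, t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vols = vols + rng.normal(0.0, noise_sd, size=vols.shape)
    return replace(dummy, volumes=vols)


# ---------------------------------------------------------------------------
# I/O: NIfTI volumes + acquisition-times CSV
# ---------------------------------------------------------------------------

_TIME_COLUMNS = ("animal_id", "t_index", "time_s")


def save_image_series(series: ImageSeries, nifti_path, times_path, animal_id: str) -> None:
    """Write one animal's series as a 4-D NIfTI file plus an acquisition-times CSV."""
    affine = np.diag([series.voxel_size] * 3 + [1.0])
    affine[:3, 3] = series.origin
    img = nib.Nifti1Image(series.volumes, affine)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(nifti_path))
    mask_img = nib.Nifti1Image(series.brain_mask.astype(np.uint8), affine)
    nib.save(mask_img, _mask_path(nifti_path))
    # NIfTI-1 headers hold geometry in float32; repeat it here at full
    # precision so a round trip reproduces the metadata exactly
    pd.DataFrame(
        {
            "animal_id": animal_id,
            "t_index": np.arange(series.times.size),
            "time_s": series.times,
            "noise_sd": series.noise_sd,
            "voxel_size_mm": repr(series.voxel_size),
            "origin_x_mm": repr(float(series.origin[0])),
            "origin_y_mm": repr(float(series.origin[1])),
            "origin_z_mm": repr(float(series.origin[2])),
        }
    ).to_csv(times_path, index=False)


def _mask_path(nifti_path) -> str:
    p = Path(nifti_path)
    stem = p.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return str(p.with_name(stem + "_mask.nii"))


def load_image_series(nifti_path, times_path) -> ImageSeries:
    """Read an image series written by :func:`save_image_series`."""
    img = nib.load(str(nifti_path))
    vols = np.asarray(img.dataobj)
    affine = img.affine
    voxel_size = float(affine[0, 0])
    origin = np.asarray(affine[:3, 3], dtype=float)
    tdf = pd.read_csv(times_path)
    for col in _TIME_COLUMNS:
        if col not in tdf.columns:
            raise ValidationError(f"times CSV {times_path}: missing required column {col!r}")
    tdf = tdf.sort_values("t_index")
    if "voxel_size_mm" in tdf.columns:  # full-precision geometry, see save
        voxel_size = float(tdf["voxel_size_mm"].iloc[0])
        origin = np.array([float(tdf[f"origin_{ax}_mm"].iloc[0]) for ax in "xyz"])
    times = tdf["time_s"].to_numpy(dtype=float)
    noise_sd = float(tdf["noise_sd"].iloc[0]) if "noise_sd" in tdf.columns else 0.0
    mask_file = _mask_path(nifti_path)
    if Path(mask_file).exists():
        mask = np.asarray(nib.load(mask_file).dataobj).astype(bool)
    else:
        mask = ellipsoid_brain_mask(vols.shape[:3])
    return ImageSeries(
        volumes=vols, times=times, voxel_size=voxel_size,
        origin=origin, brain_mask=mask, noise_sd=noise_sd,
    )
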