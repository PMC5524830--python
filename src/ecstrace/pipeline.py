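"""Config-driven end-to-end runner: cohort → rendering → estimation → statistics.

A single YAML config describes the cohort, the acquisition grid, the signal
model and the estimation/statistics settings; :func:`run` executes every
stage and writes CSV/JSON outputs plus a run manifest.  Re-running with the
same config and master seed is byte-identical on all CSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    DEFAULT_N_PER_GROUP,
    GROUP_LABELS,
    AnimalRecord,
    GridSpec,
    GroupSpec,
    cohort_to_frame,
    default_cohort_specs,
    default_times,
    render_image_series,
    save_image_series,
)
from .estimation import EstimationConfig, analyze_animal, records_to_results_frame
from .forward_model import SN_INJECTION_SITE_MM, TracerKineticParams, ValidationError, concentration
from .stats import (
    anova_from_summary,
    lsd_posthoc,
    pearson,
    summaries_from_values,
)

__all__ = ["RunConfig", "RunResult", "run", "load_config", "compute_group_stats"]

logger = logging.getLogger("ecstrace")

#: Unit caveat surfaced in every manifest: the published k' magnitudes carry
#: area-per-time units, but a first-order clearance coefficient must be a
#: rate; the printed ×10⁻⁴ values are treated as ×10⁻⁴ s⁻¹ throughout.
K_PRIME_UNIT_WARNING = (
    "k' is reported in the source tables with the same units as D* (mm²/s); "
    "a clearance rate coefficient carries 1/time, so printed ×1e-4 magnitudes "
    "are interpreted as ×1e-4 s⁻¹ internally."
)

_OBSERVABLES = ("d_eff", "k_clear", "vd_max_pct", "t_half_s")
_PEARSON_PAIRS = (("d_eff", "vd_max_pct"), ("k_clear", "t_half_s"))


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_dict`` for the schema)."""

    seed: int = 0
    output_dir: str = "ecstrace_out"
    mode: str = "mechanistic"                  # mechanistic | empirical
    n_per_group: int = DEFAULT_N_PER_GROUP
    groups: tuple[str, ...] = GROUP_LABELS
    group_overrides: dict = field(default_factory=dict)
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 0.2
    n_volumes: int = 12
    t_start_s: float = 600.0
    t_step_s: float = 900.0
    beta: float = 1e10                          # signal units per mol/mm³
    baseline: float = 100.0
    noise_frac_of_peak: float = 0.02
    mask_threshold: float = 0.05
    theta: float | None = None
    theta_noise_multiple: float = 3.0
    alpha: float = 0.2
    write_images: bool = False
    pd_group: str = "PD"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        nested: dict = {}
        for section, keys in {
            "cohort": ("mode", "n_per_group", "groups", "group_overrides"),
            "grid": ("grid_shape", "voxel_size_mm"),
            "times": ("n_volumes", "t_start_s", "t_step_s"),
            "signal": ("beta", "baseline", "noise_frac_of_peak"),
            "estimation": ("mask_threshold", "theta", "theta_noise_multiple", "alpha"),
        }.items():
            sub = raw.pop(section, {}) or {}
            unknown = set(sub) - set(keys)
            if unknown:
                raise ValidationError(f"config section {section!r}: unknown keys {sorted(unknown)}")
            nested.update(sub)
        nested.update(raw)
        unknown = set(nested) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "groups" in nested:
            nested["groups"] = tuple(nested["groups"])
        if "grid_shape" in nested:
            gs = nested["grid_shape"]
            nested["grid_shape"] = (gs,) * 3 if isinstance(gs, int) else tuple(gs)
        # YAML 1.1 reads "1.0e10" (no signed exponent) as a string; coerce scalars
        for f in dataclasses.fields(cls):
            if f.name in nested and nested[f.name] is not None:
                if f.type == "float" or f.type == "float | None":
                    nested[f.name] = float(nested[f.name])
                elif f.type == "int":
                    nested[f.name] = int(nested[f.name])
        cfg = cls(**nested)
        if cfg.mode not in ("mechanistic", "empirical"):
            raise ValidationError(f"unknown cohort mode {cfg.mode!r}")
        if cfg.noise_frac_of_peak < 0:
            raise ValidationError("noise_frac_of_peak must be >= 0")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = list(self.groups)
        d["grid_shape"] = list(self.grid_shape)
        return d

    def cohort_specs(self) -> list[GroupSpec]:
        specs = default_cohort_specs(mode=self.mode, n_per_group=self.n_per_group,
                                     labels=self.groups)
        if not self.group_overrides:
            return specs
        out = []
        for spec in specs:
            ov = self.group_overrides.get(spec.label)
            if not ov:
                out.append(spec)
                continue
            means = dict(spec.param_means, **(ov.get("param_means") or {}))
            sds = dict(spec.param_sds, **(ov.get("param_sds") or {}))
            out.append(GroupSpec(label=spec.label, n=int(ov.get("n", spec.n)),
                                 param_means=means, param_sds=sds, mode=spec.mode))
        return out

    def times(self) -> np.ndarray:
        return default_times(self.n_volumes, self.t_start_s, self.t_step_s)

    def grid(self) -> GridSpec:
        return GridSpec(shape=self.grid_shape, voxel_size=self.voxel_size_mm)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


@dataclass
class RunResult:
    output_dir: Path
    records: list[AnimalRecord]
    summaries: pd.DataFrame
    stats: dict
    manifest: dict


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _peak_enhancement(params: TracerKineticParams, grid: GridSpec, times: np.ndarray,
                      beta: float) -> float:
    """Noise-free peak enhancement: beta × C at the voxel centre nearest the source."""
    origin = grid.resolved_origin(params.center)
    rel = (np.asarray(params.center) - origin) / grid.voxel_size
    r_min = np.linalg.norm((rel - np.round(rel)) * grid.voxel_size)
    r_min = max(r_min, 1e-9)
    return float(beta * np.max(concentration(params, r_min, times)))


def simulate_and_estimate(config: RunConfig, records: list[AnimalRecord],
                          out_dir: Path | None = None) -> list[str]:
    """Render each animal's series and run the estimation chain on it in memory.

    Returns a list of warning strings for animals whose estimation failed or
    produced an undefined t_1/2.  When ``out_dir`` is given, each rendered
    series is also written as NIfTI + times CSV.
    """
    warnings: list[str] = []
    grid = config.grid()
    times = config.times()
    for rec in records:
        t0 = time.perf_counter()
        params = rec.true_params(alpha=config.alpha)
        peak = _peak_enhancement(params, grid, times, config.beta)
        noise_sd = config.noise_frac_of_peak * peak
        series = render_image_series(
            params, grid, times, beta=config.beta, baseline=config.baseline,
            noise_sd=noise_sd, seed=rec.seed,
        )
        if out_dir is not None:
            save_image_series(series, out_dir / f"{rec.animal_id}.nii",
                              out_dir / f"{rec.animal_id}_times.csv", rec.animal_id)
        est_cfg = EstimationConfig(
            baseline=config.baseline, beta=config.beta, alpha=config.alpha,
            center=params.center, mask_threshold=config.mask_threshold,
            theta=config.theta, theta_noise_multiple=config.theta_noise_multiple,
        )
        try:
            analyze_animal(series, est_cfg, record=rec)
        except (ValidationError, RuntimeError) as exc:
            rec.converged = False
            rec.diagnostics = {"error": str(exc)}
            warnings.append(f"animal {rec.animal_id}: estimation failed: {exc}")
            continue
        if not rec.diagnostics.get("t_half_defined", False):
            warnings.append(f"animal {rec.animal_id}: t_1/2 undefined within the sampled span")
        if not rec.converged:
            warnings.append(f"animal {rec.animal_id}: fit did not converge")
        logger.info("animal %s analyzed in %.2f s", rec.animal_id, time.perf_counter() - t0)
    return warnings


def group_summary_frame(records: list[AnimalRecord]) -> pd.DataFrame:
    """Mean ± SD per group per observable, mirroring the results-table layout."""
    rows = []
    frame = pd.DataFrame([
        {"group": r.group, **{k: getattr(r, k) for k in _OBSERVABLES}} for r in records
    ])
    for group, sub in frame.groupby("group", sort=False):
        for param in _OBSERVABLES:
            v = sub[param].dropna()
            rows.append({
                "group": group, "parameter": param, "n": int(v.size),
                "mean": float(v.mean()) if v.size else float("nan"),
                "sd": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
            })
    return pd.DataFrame(rows)


def compute_group_stats(records: list[AnimalRecord], pd_group: str = "PD") -> tuple[dict, list[str]]:
    """ANOVA + LSD per observable and the two within-PD Pearson analyses."""
    warnings: list[str] = []
    frame = pd.DataFrame([
        {"group": r.group, **{k: getattr(r, k) for k in _OBSERVABLES}} for r in records
    ])
    report: dict = {"anova": {}, "lsd": {}, "pearson": {}}
    for param in _OBSERVABLES:
        values = {}
        for group, sub in frame.groupby("group", sort=False):
            v = sub[param].dropna().to_numpy()
            if v.size >= 2:
                values[group] = v
        if len(values) < 2:
            warnings.append(f"{param}: fewer than two groups with data; ANOVA skipped")
            continue
        summaries = summaries_from_values(values)
        res = anova_from_summary(summaries)
        report["anova"][param] = dataclasses.asdict(res)
        if res.degenerate:
            warnings.append(f"{param}: degenerate ANOVA (zero within-group variance)")
            continue
        report["lsd"][param] = [
            dataclasses.asdict(x) for x in lsd_posthoc(summaries, res.ms_within, res.df_within)
        ]
    pd_frame = frame[frame["group"] == pd_group]
    for x_name, y_name in _PEARSON_PAIRS:
        sub = pd_frame[[x_name, y_name]].dropna()
        key = f"{x_name}_vs_{y_name}"
        if len(sub) < 3:
            warnings.append(f"pearson {key}: fewer than 3 complete animals in {pd_group}")
            continue
        try:
            res = pearson(sub[x_name].to_numpy(), sub[y_name].to_numpy())
        except ValidationError as exc:
            warnings.append(f"pearson {key}: {exc}")
            continue
        report["pearson"][key] = dataclasses.asdict(res)
    return report, warnings


def stats_report_frame(report: dict) -> pd.DataFrame:
    """Flatten the stats report into one record per test for CSV export."""
    rows = []
    for param, a in report.get("anova", {}).items():
        rows.append({"test": "anova", "parameter": param, "pair": "", **a})
    for param, pairs in report.get("lsd", {}).items():
        for x in pairs:
            rows.append({
                "test": "lsd", "parameter": param, "pair": " vs ".join(x["pair"]),
                "mean_diff": x["mean_diff"], "t_stat": x["t_stat"], "p_value": x["p_value"],
            })
    for key, c in report.get("pearson", {}).items():
        rows.append({"test": "pearson", "parameter": key, "pair": "",
                     "r": c["r"], "n": c["n"], "t_stat": c["t_stat"], "p_value": c["p_value"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write all outputs under ``config.output_dir``."""
    from .cohort import draw_cohort  # local import keeps module load light

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = [K_PRIME_UNIT_WARNING]

    t0 = time.perf_counter()
    records = draw_cohort(config.cohort_specs(), config.seed)
    logger.info("cohort of %d animals drawn", len(records))

    if config.mode == "mechanistic":
        img_dir = out / "images" if config.write_images else None
        if img_dir is not None:
            img_dir.mkdir(exist_ok=True)
        warnings += simulate_and_estimate(config, records, img_dir)

    cohort_to_frame(records).to_csv(out / "cohort.csv", index=False)
    records_to_results_frame(records).to_csv(out / "results.csv", index=False)
    summaries = group_summary_frame(records)
    summaries.to_csv(out / "group_summary.csv", index=False)

    stats_report, stat_warnings = compute_group_stats(records, pd_group=config.pd_group)
    warnings += stat_warnings
    with open(out / "stats.json", "w") as fh:
        json.dump(stats_report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    stats_report_frame(stats_report).to_csv(out / "stats.csv", index=False)

    manifest = {
        "software": {"name": "ecstrace", "version": __version__},
        "config": config.to_dict(),
        "master_seed": config.seed,
        "animal_seeds": {r.animal_id: r.seed for r in records},
        "conventions": {
            "k_clear_units": "1/s (printed x1e-4 magnitudes read as x1e-4 s^-1)",
            "t_half": "time from Vd peak to half-peak on the Vd(t) curve",
            "vd_pct_denominator": "ellipsoid brain-mask volume on the acquisition grid",
            "injection_site_mm": list(SN_INJECTION_SITE_MM),
        },
        "warnings": warnings,
        "n_animals": len(records),
        "n_failed": sum(1 for r in records if r.diagnostics.get("error")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run complete in %.1f s", time.perf_counter() - t0)
    return RunResult(output_dir=out, records=records, summaries=summaries,
                     stats=stats_report, manifest=manifest)
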