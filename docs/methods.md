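# Methods

## Forward model

The package models a bolus of Gd-DTPA (2 μl of 10 mmol/L, i.e.
Q = 2 × 10⁻⁸ mol) released instantaneously at the stereotactic injection
site in the substantia nigra (AP −4.8, ML 1.9, DV −7.8 mm from bregma).
Within the extracellular space (ECS) the tracer obeys a linear
diffusion–clearance PDE,

∂C/∂t = D\* ∇²C − k′ C,

whose free-space point-source solution is

C(r, t) = (Q/α) (4πD\*t)^(−3/2) exp(−r²/(4D\*t) − k′t).

Assumptions: homogeneous, isotropic effective diffusion; first-order
clearance uniform in space; instantaneous release (the ~2-min infusion is
short against the multi-hour observation window); no boundary effects
within the imaged region. α is the ECS volume fraction (default 0.2, the
classical rodent value); it scales the concentration amplitude only and
cancels out of D\*, k′ and t₁/₂ estimation — it matters only if the fitted
amplitude is to be read back as an absolute dose.

**Units of k′.** Published summary tables for this kind of experiment print
k′ with the same ×10⁻⁴ mm²/s scale as D\*, but a first-order clearance
coefficient must carry 1/time. The package treats the printed ×10⁻⁴
magnitudes as ×10⁻⁴ s⁻¹ throughout, and the pipeline manifest repeats this
convention as a warning in every run.

### Distribution volume

The suprathreshold radius solves C(r\*, t) = θ in closed form:

r\*² = 4D\*t [ ln(Q / (α(4πD\*t)^{3/2}θ)) − k′t ],  clipped at 0,

giving Vd(t) = (4/3)π r\*³ and Vd% = 100·Vd/V_ref. The reference volume
V_ref is the brain-mask volume (see below); published work rarely states
this denominator, so it is an explicit convention here, recorded in the run
manifest. Curve metrics:

* Vd-max: curve maximum; arg-max ties resolve to the earliest time;
* t_max: time of the maximum;
* t₁/₂: duration from t_max to the first crossing of Vd-max/2, linearly
  interpolated between bracketing samples. If the sampled span ends above
  half-maximum, t₁/₂ is *undefined* — flagged (NaN), never extrapolated.

Variants of a "half-life" (local signal half-life at a voxel; half-life of
the α-integrated total content, which is exactly ln 2/k′) are conceptually
distinct from the Vd-curve definition used here; the Vd-curve definition is
the package-wide default because Vd(t) is what dynamic imaging actually
measures.

### Finite-difference oracle

`fd_oracle` integrates the same PDE with an explicit 7-point scheme from
the analytic field at t_start, with absorbing far boundaries, as an
*independent* check on the closed form. Stability requires
D\*Δt/Δx² ≤ 1/6; violating steps raise an error stating the admissible Δt.
Accuracy is limited by stencil dispersion of the sharp early Gaussian: the
validation setting (64³ voxels, Δx = 0.1 mm, t_start = 900 s, report at
1800 s) keeps the maximum relative error below 1% on voxels holding ≥ 1% of
peak concentration. Coarser grids (0.2 mm) or earlier starts leave 2–5%
tail errors and are not used for validation claims.

## Synthetic cohort

The generator emulates the four-group study design:

| group    | D\* (×10⁻⁴ mm²/s) | k′ (×10⁻⁴ s⁻¹) | Vd-max% | t₁/₂ (min) |
|----------|-------------------|-----------------|---------------|---------------|
| PD       | 2.744 ± 0.341     | 2.153 ± 0.610   | 2.392 ± 0.185 | 97.8 ± 11.9 |
| Madopar  | 2.340 ± 0.448     | 1.109 ± 0.333   | 2.153 ± 0.102 | 84.1 ± 8.2  |
| sham     | 2.078 ± 0.326     | 0.879 ± 0.262   | 2.091 ± 0.110 | 67.4 ± 7.2  |
| control  | 2.023 ± 0.501     | 0.854 ± 0.355   | 2.054 ± 0.090 | 69.6 ± 7.0  |

Per-animal parameters are independent normal draws with these means/SDs,
truncated at zero. Two modes exist: *mechanistic* draws (D\*, k′) only and
leaves the macroscopic observables to the estimation pipeline; *empirical*
draws all four observables directly so the statistics stage can be
exercised in isolation.

**n = 9 per group.** Ten animals per group entered the study, but
behavioural screening implies attrition and the final n is not stated.
Re-deriving the one-way F statistic from the published means/SDs at each
equal n in {5..10} shows n = 9 is the only value reproducing all four
published F values (within 0.1%); the `audit_equal_n` function makes this
reconstruction reproducible rather than folklore. Note an internal tension
in the source: the published Pearson p-values (p = 0.032 at r = 0.675,
p = 0.022 at r = −0.708) correspond to n = 10, while the F statistics
require n = 9. The package logs this; it does not attempt to resolve it.

**Imaging model.** Acquisition physics is out of scope; a volume at time t
is baseline + β·C(r, t) + ε with ε ~ N(0, σ²) i.i.d. per voxel and frame
(additive Gaussian, appropriate to the post-enhancement SNR regime; Rician
noise floors, motion and registration error are not modelled). Defaults:
64³ voxels at 0.2 mm (a 12.8 mm cube around the injection site), 12 volumes
15 min apart starting 10 min post-injection, σ = 2% of the peak
enhancement, β = 10¹⁰ signal units per mol/mm³, baseline 100. The brain
mask is a centred ellipsoid with semi-axes 45% of each grid extent
(≈ 800 mm³), and its voxelised volume is the Vd% denominator. The detection
threshold θ defaults to the concentration whose enhancement equals 3× the
noise SD; noise-free analyses must set θ explicitly.

Because the forward model is a single-compartment point source, the
synthetic observables are internally consistent with (D\*, k′) by
construction: higher k′ always means smaller Vd-max% and shorter t₁/₂. The
published cross-group pattern (the PD group showing the *highest* k′ and
the *longest* t₁/₂ simultaneously) cannot arise from this model, so the
generator's mechanistic mode makes no attempt to reproduce all four group
means jointly; the group tables for Vd-max% and t₁/₂ are used in empirical
mode only. Passing tests therefore demonstrate estimator correctness on
model-consistent data, not fidelity of the single-compartment model to the
in-vivo measurements.

**Seeding.** A master seed spawns per-animal sub-seeds by mixing a CRC of
"(group label, within-group index)", so cohorts are stable under group
reordering and the whole cohort→render→estimate→stats path is bit
reproducible.

## Estimation

Per animal: concentration = (signal − baseline)/β, clipped at 0; then the
point-source fit; then voxel-count Vd.

The fit minimises squared residuals of the model against the data over
suprathreshold voxels (default threshold: 5% of the per-series peak) with
bounds D\* ∈ [10⁻⁵, 10⁻²] mm²/s, k′ ∈ [0, 10⁻²] s⁻¹ (a generous physical
envelope), objective tolerance 10⁻¹⁰, at most 200 function evaluations.
Two numerical choices matter at realistic noise and were adopted after
measuring their effect:

1. **Voxel selection must not follow the noise.** Thresholding the
   *observed* field at 5% of peak (2.5σ at 2% noise) admits thousands of
   isolated noise-only voxels scattered through the volume, which wrecks
   the fit (errors of order 100%). The initial sample therefore keeps only
   the suprathreshold component spatially connected to the injection site
   (the tracer cloud is one connected region around the source), and the
   refinement stages re-select voxels where the *fitted model* exceeds the
   threshold — a selection independent of the noise realisation.
2. **Final residuals are linear-scale.** A log-transformed objective is
   attractive for its dynamic range and yields the linearised initial
   guess (ordinary regression of log C + (3/2)log t on {r²/t, t}), but
   under additive noise E[log(C+ε)] < log C at faint voxels, which biases
   k′ upward by ~25% and D\* downward at 2% noise. The refinement
   therefore minimises (C_model − C_obs)/peak, which is unbiased for
   additive Gaussian noise. Selection and fit alternate three times.

With these choices, noise-free recovery is exact to ≲10⁻¹⁴ relative and at
2% noise the mean of 20 replicates recovers both parameters to ~0.1–0.3%
(per-replicate median |error| 0.1–3.3%, the larger figure for the small
control-group k′).

Vd is measured by counting in-mask voxels with C ≥ θ (no connectivity
filter — this mirrors simple threshold-based reading of enhancement maps;
at 3× noise the spurious count adds a small constant floor, one reason the
absolute Vd-max% depends on convention). Non-convergence of the fit is
flagged in diagnostics, not raised; an undefined t₁/₂ is NaN plus a flag.

## Group statistics

From per-group (n, mean, SD): MS_between = Σnᵢ(mᵢ−m̄)²/(g−1) with the
n-weighted grand mean, MS_within = Σ(nᵢ−1)sᵢ²/Σ(nᵢ−1), F on
(g−1, Σnᵢ−g) df — algebraically identical to the raw-data ANOVA (tested to
10⁻¹⁰). Fisher LSD: pairwise t on the pooled error term, two-sided,
unadjusted. Pearson inference uses the exact t transform on n−2 df. All
p-values are two-sided (sidedness is not stated in the source tables).
A pooled variance below 10⁻¹² of the between-group scale is treated as
degenerate (F undefined and flagged) so that cohorts of bit-identical
animals do not yield meaningless astronomical F values.

## Pipeline

`run(config)` executes draw → render → estimate → statistics and writes
cohort, per-animal results, group-summary and statistics tables plus a
manifest (config, per-animal seeds, conventions, warnings, software
version). Outputs are byte-identical under a fixed master seed; timings go
to the logger, never into outputs. Failed animals are recorded with
diagnostics and the run continues. Rendered images are kept in memory by
default (a full 36-animal cohort of 64³×12 float64 volumes is ~0.9 GB on
disk); `write_images` persists them as NIfTI when wanted.

## Problem sizes

Defaults were chosen so a full simulated cohort (36 animals, 64³ grid,
12 frames) runs in well under a minute on one CPU and the complete test
suite — including the 4-group × 20-replicate noisy recovery sweep, the 64³
finite-difference validation and 10⁴-simulation null calibrations of the
ANOVA and Pearson tests — in a few minutes. The acceptance script uses the
same grid, schedule and 20 replicates.

## Known limitations

* Single-compartment, homogeneous, isotropic model: no tortuosity
  decomposition, anisotropy, spatial heterogeneity or BBB exchange.
* Linear enhancement map; no MR sequence simulation or relaxivity
  saturation; Gaussian (not Rician) noise.
* Vd-max% and t₁/₂ depend on the detection-threshold and reference-volume
  conventions; comparisons across conventions are not meaningful.
* The estimator assumes the injection site is known (true in the synthetic
  setting; in real data it would come from the electrode/needle track).
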