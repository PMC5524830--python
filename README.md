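# ecstrace

Tracer-kinetic quantification of diffusion and clearance in brain
extracellular space (ECS) from dynamic contrast image series.

When a small extracellular tracer such as Gd-DTPA is injected as a bolus
into brain tissue (here: the rat substantia nigra), serial T1-weighted MRI
shows the tracer cloud spreading and fading. Four parameters summarise that
process:

* **D\*** — effective diffusion coefficient (mm²/s): how fast the tracer
  spreads through the tortuous ECS;
* **k′** — clearance coefficient (1/s): the first-order rate at which the
  tracer is removed (cellular uptake, perivascular drainage);
* **Vd-max%** — peak distribution volume, the largest tissue volume in
  which the tracer is detectable, as a percentage of a reference brain
  volume;
* **t₁/₂** — half-life of the distribution volume: time from its peak until
  it falls to half the peak.

`ecstrace` is for researchers who analyse such experiments or want to study
the estimator itself. It provides:

1. a **forward model** — the instantaneous point-source solution of
   ∂C/∂t = D\*∇²C − k′C,

   C(r, t) = (Q/α) (4πD\*t)^(−3/2) exp(−r²/(4D\*t) − k′t),

   for dose Q released into ECS volume fraction α, together with the
   distribution-volume curve Vd(t) = (4/3)π r\*(t)³ above a detection
   threshold, and an independent finite-difference PDE integrator used to
   validate the closed form;
2. a **synthetic cohort generator** that emulates the four-group study
   design (PD model, Madopar-treated, sham, control; n = 9 per group) with
   per-animal parameters drawn around the published group means/SDs and
   rendered as noisy 4-D image series (NIfTI + acquisition-time CSV);
3. a per-animal **estimator** that inverts the enhancement model, fits
   (D\*, k′, amplitude) to the suprathreshold voxels by bounded nonlinear
   least squares, and measures (Vd-max%, t₁/₂) by voxel counting;
4. **group statistics from first principles** — one-way ANOVA (raw and
   summary-statistics forms), Fisher-LSD post-hoc tests, Pearson
   correlation inference, and a sample-size auditor that checks which equal
   per-group n is consistent with a published summary table.

## Worked example

Simulate one noisy animal with the PD-group mean kinetics and recover its
parameters end to end:

```python
from ecstrace import (TracerKineticParams, GridSpec, render_image_series,
                      EstimationConfig, analyze_animal, default_times)

truth = TracerKineticParams(d_eff=2.744e-4, k_clear=2.153e-4)   # PD means
grid = GridSpec()              # 64³ voxels at 0.2 mm around the SN site
times = default_times()        # 12 volumes, 15 min apart, first at 10 min
clean = render_image_series(truth, grid, times, beta=1e10, baseline=100.0)
noise_sd = 0.02 * float((clean.volumes - 100.0).max())   # 2% of peak
series = render_image_series(truth, grid, times, beta=1e10, baseline=100.0,
                             noise_sd=noise_sd, seed=7)
rec = analyze_animal(series, EstimationConfig(baseline=100.0, beta=1e10,
                                              center=truth.center))
print(f"D*      = {rec.d_eff*1e4:.3f} x 1e-4 mm^2/s   (truth 2.744)")
print(f"k'      = {rec.k_clear*1e4:.3f} x 1e-4 s^-1    (truth 2.153)")
print(f"Vd-max% = {rec.vd_max_pct:.2f} %")
print(f"t_1/2   = {rec.t_half_s/60:.1f} min")
```

```
D*      = 2.737 x 1e-4 mm^2/s   (truth 2.744)
k'      = 2.095 x 1e-4 s^-1    (truth 2.153)
Vd-max% = 1.93 %
t_1/2   = 16.2 min
```

D\* and k′ come back within a few tenths of a percent / a few percent of
the generator truth at this noise level; Vd-max% and t₁/₂ are consistent
with the model's own Vd(t) curve at the 3×noise detection threshold (their
absolute size depends on the threshold and reference-volume conventions —
see `docs/methods.md`).

Reconstructing a one-way ANOVA from a published summary table needs only
per-group (n, mean, SD):

```python
from ecstrace import GroupSummary, anova_from_summary
table = {"PD": (2.744, 0.341), "Madopar": (2.340, 0.448),
         "sham": (2.078, 0.326), "control": (2.023, 0.501)}
res = anova_from_summary([GroupSummary(g, 9, m, s) for g, (m, s) in table.items()])
print(f"F = {res.f_stat:.3f}, p = {res.p_value:.4f}")
```

```
F = 5.779, p = 0.0028  (published: F = 5.774, p = 0.0025)
```

A full cohort run (simulate → estimate → statistics) is driven by a YAML
config:

```sh
ecstrace run config.yaml        # writes cohort.csv, results.csv,
                                # group_summary.csv, stats.json, manifest.json
ecstrace audit-n summaries.csv --f-csv printed_f.csv
```

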