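"""Per-animal estimation chain: inversion, point-source fit, Vd counting."""

import numpy as np
import pytest

from ecstrace import (
    GROUP_PARAM_TABLE,
    EstimationConfig,
    TracerKineticParams,
    ValidationError,
    analyze_animal,
    fit_point_source,
    signal_to_concentration,
    vd_from_series,
    vd_radius,
)
from ecstrace.cohort import GridSpec, default_times, render_image_series

BETA = 1e10
BASELINE = 100.0
THETA = 2e-9


class TestSignalToConcentration:
    def test_inverse_consistency(self, pd_series_clean, pd_params):
        # far-field concentrations below the float resolution of the baseline
        # signal (eps(baseline)/beta) are unrecoverable by construction
        conc = signal_to_concentration(pd_series_clean, BASELINE, BETA)
        r = pd_series_clean.voxel_distances(pd_params.center)
        k = 2
        from ecstrace import concentration

        expected = np.asarray(concentration(pd_params, r, pd_series_clean.times[k]))
        quantum = np.finfo(float).eps * BASELINE / BETA
        np.testing.assert_allclose(conc.conc[..., k], expected,
                                   rtol=1e-9, atol=4 * quantum)

    def test_all_baseline_maps_to_zero(self, pd_series_clean):
        flat = pd_series_clean
        vols = np.full_like(flat.volumes[..., :3], BASELINE)
        from ecstrace.cohort import ImageSeries

        series = ImageSeries(
            volumes=vols, times=flat.times[:3], voxel_size=flat.voxel_size,
            origin=flat.origin, brain_mask=flat.brain_mask, noise_sd=0.0,
        )
        conc = signal_to_concentration(series, BASELINE, BETA)
        assert np.all(conc.conc == 0.0)

    def test_negative_excursions_clipped(self, pd_params):
        grid = GridSpec(shape=(16, 16, 16), voxel_size=0.4)
        series = render_image_series(
            pd_params, grid, np.array([600.0, 1200.0, 1800.0]),
            beta=BETA, baseline=BASELINE, noise_sd=25.0, seed=4,
        )
        conc = signal_to_concentration(series, BASELINE, BETA)
        assert conc.conc.min() == 0.0

    def test_invalid_beta(self, pd_series_clean):
        with pytest.raises(ValidationError):
            signal_to_concentration(pd_series_clean, BASELINE, 0.0)


class TestFitPointSource:
    def test_noise_free_recovery_control_group(self, grid, times):
        """Control-group mean kinetics recovered to < 0.5% from a clean series."""
        p = TracerKineticParams(d_eff=2.023e-4, k_clear=0.854e-4)
        series = render_image_series(p, grid, times, beta=BETA, baseline=BASELINE)
        conc = signal_to_concentration(series, BASELINE, BETA)
        fit = fit_point_source(conc, p.center)
        assert fit.diagnostics["converged"]
        assert fit.d_eff == pytest.approx(p.d_eff, rel=5e-3)
        assert fit.k_clear == pytest.approx(p.k_clear, rel=5e-3)

    def test_amplitude_shape_separation(self, pd_params, grid, times):
        """Doubling beta rescales dose_eff proportionally, leaves D*, k' unchanged."""
        s1 = render_image_series(pd_params, grid, times, beta=BETA, baseline=BASELINE)
        s2 = render_image_series(pd_params, grid, times, beta=2 * BETA, baseline=BASELINE)
        f1 = fit_point_source(signal_to_concentration(s1, BASELINE, BETA), pd_params.center)
        f2 = fit_point_source(signal_to_concentration(s2, BASELINE, BETA), pd_params.center)
        assert f2.dose_eff / f1.dose_eff == pytest.approx(2.0, rel=1e-6)
        assert f2.d_eff == pytest.approx(f1.d_eff, rel=1e-6)
        assert f2.k_clear == pytest.approx(f1.k_clear, abs=1e-6 * f1.k_clear + 1e-12)

    def test_monte_carlo_recovery_at_two_percent_noise(
        self, pd_params, grid, times, pd_noise_sd
    ):
        """20 seeded replicates at 2% noise: median relative error < 5% for both."""
        d_errs, k_errs = [], []
        for i in range(20):
            series = render_image_series(
                pd_params, grid, times, beta=BETA, baseline=BASELINE,
                noise_sd=pd_noise_sd, seed=5000 + i,
            )
            fit = fit_point_source(signal_to_concentration(series, BASELINE, BETA),
                                   pd_params.center)
            d_errs.append(abs(fit.d_eff / pd_params.d_eff - 1.0))
            k_errs.append(abs(fit.k_clear / pd_params.k_clear - 1.0))
        assert np.median(d_errs) < 0.05
        assert np.median(k_errs) < 0.05

    def test_no_suprathreshold_voxels_is_fit_error(self, pd_series_clean):
        from ecstrace import FitError

        conc = signal_to_concentration(pd_series_clean, BASELINE, BETA)
        zeroed = conc
        zeroed.conc = np.zeros_like(conc.conc)
        with pytest.raises(FitError):
            fit_point_source(zeroed, (0.0, 0.0, 0.0))


class TestVdFromSeries:
    def test_voxel_count_matches_analytic_volume(self, pd_params, pd_series_clean):
        """Counted Vd within one voxel-shell volume of (4/3)π r*³ at every time."""
        conc = signal_to_concentration(pd_series_clean, BASELINE, BETA)
        curve = vd_from_series(conc, THETA)
        dx = pd_series_clean.voxel_size
        for k, t in enumerate(pd_series_clean.times):
            r_star = vd_radius(pd_params, THETA, t)
            analytic = 4.0 / 3.0 * np.pi * r_star**3
            shell = 4.0 * np.pi * max(r_star, dx) ** 2 * dx
            assert abs(curve.vd[k] - analytic) <= shell + dx**3

    def test_threshold_above_peak_gives_flat_zero_curve(self, pd_series_clean):
        conc = signal_to_concentration(pd_series_clean, BASELINE, BETA)
        curve = vd_from_series(conc, 10.0 * conc.conc.max())
        assert np.all(curve.vd == 0.0)
        assert curve.vd_max_pct == 0.0

    def test_mesh_refinement_converges_to_analytic(self, pd_params):
        """Halving voxel size 0.4 → 0.2 → 0.1 mm shrinks the Vd error.

        Aggregated over several times and thresholds: a single (t, theta)
        pair can fluctuate with how the threshold surface happens to cut the
        voxel lattice."""
        t = np.array([600.0, 900.0, 1200.0, 1500.0, 1800.0])
        thetas = (1.5e-9, 2e-9, 3e-9)
        errors = []
        for dx, n in ((0.4, 24), (0.2, 48), (0.1, 96)):
            grid = GridSpec(shape=(n, n, n), voxel_size=dx)
            series = render_image_series(pd_params, grid, t, beta=BETA, baseline=BASELINE)
            conc = signal_to_concentration(series, BASELINE, BETA)
            total = 0.0
            for theta in thetas:
                curve = vd_from_series(conc, theta)
                analytic = 4.0 / 3.0 * np.pi * np.asarray(
                    [vd_radius(pd_params, theta, tt) for tt in t]) ** 3
                total += float(np.abs(curve.vd - analytic).sum())
            errors.append(total)
        assert errors[0] > errors[1] > errors[2]

    def test_empty_mask_rejected(self, pd_series_clean):
        conc = signal_to_concentration(pd_series_clean, BASELINE, BETA)
        with pytest.raises(ValidationError):
            vd_from_series(conc, THETA, brain_mask=np.zeros(conc.conc.shape[:3], bool))


class TestAnalyzeAnimal:
    def test_closed_loop_on_clean_series(self, pd_params, pd_series_clean):
        """End-to-end on a noise-free animal reproduces its generator kinetics."""
        cfg = EstimationConfig(baseline=BASELINE, beta=BETA,
                               center=pd_params.center, theta=THETA)
        rec = analyze_animal(pd_series_clean, cfg)
        assert rec.converged
        assert rec.d_eff == pytest.approx(pd_params.d_eff, rel=5e-3)
        assert rec.k_clear == pytest.approx(pd_params.k_clear, rel=5e-3)
        assert 0.0 < rec.vd_max_pct < 100.0
        assert rec.t_half_s > 0.0

    def test_clearance_ordering_survives_estimation(self, grid, times):
        """Of two animals differing only in k', the faster-clearing one ends with
        smaller Vd-max% and shorter t_1/2."""
        recs = []
        for k in (1.0e-4, 2.5e-4):
            p = TracerKineticParams(d_eff=2.3e-4, k_clear=k)
            series = render_image_series(p, grid, times, beta=BETA, baseline=BASELINE)
            cfg = EstimationConfig(baseline=BASELINE, beta=BETA, center=p.center, theta=THETA)
            recs.append(analyze_animal(series, cfg))
        slow, fast = recs
        assert fast.vd_max_pct < slow.vd_max_pct
        assert fast.t_half_s < slow.t_half_s

    def test_noise_free_without_theta_is_an_error(self, pd_series_clean, pd_params):
        cfg = EstimationConfig(baseline=BASELINE, beta=BETA, center=pd_params.center)
        with pytest.raises(ValidationError, match="theta"):
            analyze_animal(pd_series_clean, cfg)


class TestParameterRecoverySweep:
    @pytest.mark.parametrize("label", sorted(GROUP_PARAM_TABLE))
    def test_noise_free_recovery_across_group_means(self, label, grid, times):
        """All four group-mean parameter pairs recovered to < 0.5% noise-free."""
        table = GROUP_PARAM_TABLE[label]
        p = TracerKineticParams(d_eff=table["d_eff"][0], k_clear=table["k_clear"][0])
        series = render_image_series(p, grid, times, beta=BETA, baseline=BASELINE)
        fit = fit_point_source(signal_to_concentration(series, BASELINE, BETA), p.center)
        assert fit.d_eff == pytest.approx(p.d_eff, rel=5e-3)
        assert fit.k_clear == pytest.approx(p.k_clear, rel=5e-3)
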