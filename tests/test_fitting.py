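"""Inverse-problem tests: normalisation, AIF extraction, 2CFM and clearance fits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from renogfr.fitting import (
    MonoexponentialClearanceModel,
    baseline_normalize,
    extract_aif,
    fit_clearance,
    fit_map,
    fit_voxel,
)
from renogfr.io_types import (
    DegenerateFitError,
    DynamicSeries,
    FluorescenceTrace,
    RoiMask,
    TwoCfmParams,
    ValidationError,
)
from renogfr.pk_models import twocfm_concentration, twocfm_concentration_ode
from renogfr.synthetic_data import (
    AifParams,
    PhantomSpec,
    TraceSpec,
    make_aif,
    make_phantom,
    make_trace,
)


class TestBaselineNormalize:
    def test_constant_voxel_becomes_zero(self):
        data = np.full((2, 2, 1, 10), 100.0)
        s = DynamicSeries(data, np.arange(10.0), (1, 1, 1), 3)
        out = baseline_normalize(s)
        assert np.all(out.data == 0.0)

    def test_baseline_window_mean_is_zero_per_voxel(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(50, 150, size=(3, 3, 2, 20))
        s = DynamicSeries(data, np.arange(20.0), (1, 1, 1), 5)
        out = baseline_normalize(s)
        np.testing.assert_allclose(out.data[..., :5].mean(axis=-1), 0.0,
                                   atol=1e-12)

    @given(st.floats(min_value=-1e3, max_value=1e3, allow_nan=False))
    def test_shift_invariance(self, c):
        """Adding a constant to a voxel's series leaves the output unchanged."""
        rng = np.random.default_rng(1)
        data = rng.uniform(0, 10, size=(2, 2, 1, 12))
        s1 = DynamicSeries(data, np.arange(12.0), (1, 1, 1), 4)
        s2 = DynamicSeries(data + c, np.arange(12.0), (1, 1, 1), 4)
        np.testing.assert_allclose(baseline_normalize(s1).data,
                                   baseline_normalize(s2).data, atol=1e-9)

    def test_normalized_phantom_voxel_equals_concentration(self, small_phantom):
        series, mask, _, spec = small_phantom
        out = baseline_normalize(series)
        aif = make_aif(series.times, spec.aif_params)
        expected = twocfm_concentration(spec.truth["cortex_right"], aif,
                                        series.times)
        voxel = np.argwhere(mask.voxels("cortex_right"))[0]
        np.testing.assert_allclose(out.data[tuple(voxel)], expected,
                                   atol=1e-10)


class TestExtractAif:
    def test_noise_free_recovery_is_exact(self, small_phantom):
        series, mask, _, spec = small_phantom
        out = baseline_normalize(series)
        aif = extract_aif(out, mask)
        truth = make_aif(series.times, spec.aif_params)
        np.testing.assert_allclose(aif.conc, truth.conc, atol=1e-10)

    def test_missing_aorta_label_rejected(self, small_phantom):
        series, mask, _, _ = small_phantom
        bad = RoiMask(np.zeros_like(mask.labels),
                      {"background": 0, "aorta": 1})
        with pytest.raises(ValidationError):
            extract_aif(series, bad)

    def test_larger_roi_reduces_noise(self):
        """Averaging 50 aorta voxels beats 1 voxel against the true AIF."""
        spec = PhantomSpec(shape=(24, 16, 8), n_volumes=120, noise_sigma=3.0,
                           seed=42)
        series, mask, _ = make_phantom(spec)
        out = baseline_normalize(series)
        truth = make_aif(series.times, spec.aif_params).conc
        sel = np.argwhere(mask.voxels("aorta"))
        assert len(sel) >= 50
        one = out.data[tuple(sel[0])]
        many = out.data[mask.voxels("aorta"), :][:50].mean(axis=0)
        rms_one = np.sqrt(np.mean((one - truth) ** 2))
        rms_many = np.sqrt(np.mean((many - truth) ** 2))
        assert rms_many < rms_one


class TestFitVoxel:
    def test_noise_free_recovery_within_one_percent(self, times, aif,
                                                    cortex_truth,
                                                    fast_fit_config):
        curve = twocfm_concentration(cortex_truth, aif, times)
        p, chi2 = fit_voxel(curve, aif, times, config=fast_fit_config)
        for name in ("F_P", "V_P", "F_T", "T_T"):
            got, want = getattr(p, name), getattr(cortex_truth, name)
            assert got == pytest.approx(want, rel=0.01)
        assert chi2 < 1e-10 * float(np.dot(curve, curve))

    def test_all_zero_curve_plasma_flow_at_lower_bound(self, times, aif,
                                                       fast_fit_config):
        """A flat curve drives F_P to its lower bound and chi2 to ~0; F_T is
        unidentifiable once no tracer enters, so only the effective model
        curve (not its value) is constrained."""
        p, chi2 = fit_voxel(np.zeros_like(times), aif, times,
                            config=fast_fit_config)
        assert p.F_P <= 0.01
        assert chi2 == pytest.approx(0.0, abs=1e-6)
        model = twocfm_concentration(p, aif, times)
        assert np.max(np.abs(model)) < 1e-3

    def test_delay_recovered_from_grid(self, times, aif, fast_fit_config):
        truth = TwoCfmParams(F_P=180.0, V_P=22.0, F_T=68.0, T_T=120.0,
                             delay=5.0)
        curve = twocfm_concentration(truth, aif, times)
        cfg = {"delay_grid": (0.0, 2.5, 5.0, 7.5), "n_starts": 2}
        p, _ = fit_voxel(curve, aif, times, config=cfg)
        assert p.delay == pytest.approx(5.0)
        assert p.F_T == pytest.approx(68.0, rel=0.01)

    def test_refit_at_optimum_matches_ode_oracle(self, times, aif,
                                                 cortex_truth,
                                                 fast_fit_config):
        """chi2 changes by < 1e-6 relative when the optimum is re-evaluated
        with the independent ODE integrator."""
        curve = twocfm_concentration(cortex_truth, aif, times)
        noisy = curve + np.random.default_rng(5).normal(
            0, 0.02 * curve.max(), curve.shape)
        p, chi2 = fit_voxel(noisy, aif, times, config=fast_fit_config)
        c_ode = twocfm_concentration_ode(p, aif, times)
        chi2_ode = float(np.sum((noisy - c_ode) ** 2))
        assert chi2_ode == pytest.approx(chi2, rel=1e-6)


class TestFitMap:
    def test_noise_free_map_matches_truth(self, small_phantom,
                                          fast_fit_config):
        series, mask, truth, _ = small_phantom
        out = baseline_normalize(series)
        aif = extract_aif(out, mask)
        maps = fit_map(out, mask, aif, config=fast_fit_config,
                       roles=("cortex_left", "cortex_right"))
        for role in ("cortex_left", "cortex_right"):
            sel = mask.voxels(role)
            assert np.all(maps.fitted_mask[sel])
            np.testing.assert_allclose(maps["F_T"][sel], truth["F_T"][sel],
                                       rtol=0.01)

    def test_region_means_ordered_as_truth(self, small_phantom,
                                           fast_fit_config):
        """Left cortex (true F_T 61) fits below right cortex (true 68)."""
        series, mask, _, _ = small_phantom
        out = baseline_normalize(series)
        aif = extract_aif(out, mask)
        maps = fit_map(out, mask, aif, config=fast_fit_config,
                       roles=("cortex_left", "cortex_right"))
        left = maps["F_T"][mask.voxels("cortex_left")].mean()
        right = maps["F_T"][mask.voxels("cortex_right")].mean()
        assert left < right

    def test_fitted_mask_subset_of_kidney_labels(self, small_phantom,
                                                 fast_fit_config):
        series, mask, _, _ = small_phantom
        out = baseline_normalize(series)
        aif = extract_aif(out, mask)
        maps = fit_map(out, mask, aif, config=fast_fit_config,
                       roles=("cortex_left",))
        kidney = mask.voxels("cortex_left")
        assert np.all(kidney[maps.fitted_mask])

    def test_chi2_nonnegative_and_zero_iff_interpolating(self, small_phantom,
                                                         fast_fit_config):
        series, mask, _, _ = small_phantom
        out = baseline_normalize(series)
        aif = extract_aif(out, mask)
        maps = fit_map(out, mask, aif, config=fast_fit_config,
                       roles=("cortex_left",))
        vals = maps.chi2[maps.fitted_mask]
        assert np.all(vals >= 0)
        # noise-free curves are interpolated: chi2 ~ 0
        assert np.all(vals < 1e-8)


class TestFitClearance:
    def test_noise_free_exact_recovery(self):
        """Instantaneous-rise trace: t_half and background recovered ~exactly."""
        spec = TraceSpec(noise_sigma=0.0, t_half=25.0,
                         distribution_phase=1e-6)
        fit = fit_clearance(make_trace(spec))
        assert fit.background == pytest.approx(120.0, abs=1e-9)
        assert fit.t_half == pytest.approx(25.0, rel=1e-6)

    def test_distribution_phase_bias_is_small(self):
        """With a 3-min distribution phase the one-compartment fit is biased
        by well under 1% — the model-misfit floor of the method."""
        fit = fit_clearance(make_trace(TraceSpec(noise_sigma=0.0)))
        assert fit.t_half == pytest.approx(25.0, rel=0.01)

    def test_constant_trace_degenerate(self):
        trace = make_trace(TraceSpec(background=100.0, amplitude=0.0))
        with pytest.raises(DegenerateFitError):
            fit_clearance(trace)

    def test_rising_tail_degenerate(self):
        t = np.arange(0.0, 2000.0)
        signal = 100.0 + np.where(t > 60.0, 0.05 * (t - 60.0), 0.0)
        trace = FluorescenceTrace(t, signal)
        with pytest.raises(DegenerateFitError):
            fit_clearance(trace)

    def test_noisy_recovery_within_one_percent(self):
        spec = TraceSpec(noise_sigma=9.0, seed=17, distribution_phase=1e-6)
        fit = fit_clearance(make_trace(spec))
        assert fit.t_half == pytest.approx(25.0, rel=0.01)

    @given(st.floats(min_value=-50.0, max_value=500.0, allow_nan=False))
    def test_offset_invariance(self, c):
        """Adding a constant to the whole trace is absorbed by background."""
        spec = TraceSpec(noise_sigma=0.0, distribution_phase=1e-6)
        trace = make_trace(spec)
        shifted = FluorescenceTrace(trace.times, trace.signal + c,
                                    trace.background_window)
        f0 = fit_clearance(trace)
        f1 = fit_clearance(shifted)
        assert f1.t_half == pytest.approx(f0.t_half, rel=1e-9)
        assert f1.background - f0.background == pytest.approx(c, abs=1e-9)

    def test_sklearn_estimator_surface(self):
        """get_params/set_params/clone work and predict matches the model."""
        from sklearn.base import clone
        est = MonoexponentialClearanceModel(fit_lag_s=200.0)
        est2 = clone(est)
        assert est2.get_params()["fit_lag_s"] == 200.0
        spec = TraceSpec(noise_sigma=0.0, distribution_phase=1e-6)
        trace = make_trace(spec)
        est2.set_params(background_window=(0.0, 60.0))
        est2.fit(trace.times, trace.signal)
        assert est2.t_half_min_ == pytest.approx(25.0, rel=1e-6)
        pred = est2.predict(np.array([est2.fit_window_[0]]))
        assert pred[0] == pytest.approx(est2.background_ + est2.amplitude_)
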