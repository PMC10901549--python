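import numpy as np
import pytest

import flimclass as fc
from flimclass.decaymodel import DecayParams, forward_model
from flimclass.fitting import (
    average_decay_curve,
    fit_biexponential,
    fit_cells,
    mean_lifetime,
    tau_m_image,
)
from flimclass.simulate import simulate_decay


class TestForwardModel:
    def test_identical_to_noiseless_simulation(self, axis, irf):
        p = DecayParams(tau1_ps=420.0, tau2_ps=1750.0, alpha1=0.72, amplitude=5e4)
        np.testing.assert_array_equal(
            forward_model(p, irf, axis),
            simulate_decay(p, irf, axis, noiseless=True),
        )

    def test_alpha1_zero_is_pure_long_lifetime(self, axis, irf):
        p0 = DecayParams(tau1_ps=400.0, tau2_ps=1800.0, alpha1=0.0, amplitude=1e4)
        mono = DecayParams(
            tau1_ps=1799.9999, tau2_ps=1800.0, alpha1=0.0, amplitude=1e4
        )
        np.testing.assert_allclose(
            forward_model(p0, irf, axis), forward_model(mono, irf, axis), rtol=1e-6
        )

    def test_integral_equals_amplitude_plus_offset(self, axis, irf):
        p = DecayParams(
            tau1_ps=400.0, tau2_ps=1800.0, alpha1=0.7, amplitude=1e5, offset=3.0
        )
        total = forward_model(p, irf, axis).sum()
        assert total == pytest.approx(1e5 + 3.0 * axis.n_bins, rel=1e-6)


class TestFitBiexponential:
    def test_noiseless_recovery_within_one_percent(self, axis, irf):
        truth = DecayParams(tau1_ps=400.0, tau2_ps=1800.0, alpha1=0.7, amplitude=1e5)
        counts = forward_model(truth, irf, axis)
        fit = fit_biexponential(counts, irf, axis)
        assert fit.converged
        assert fit.params.tau1_ps == pytest.approx(400.0, rel=0.01)
        assert fit.params.tau2_ps == pytest.approx(1800.0, rel=0.01)
        assert fit.params.alpha1 == pytest.approx(0.7, abs=0.007)

    def test_fit_from_truth_is_fixed_point(self, axis, irf):
        truth = DecayParams(tau1_ps=450.0, tau2_ps=1600.0, alpha1=0.6, amplitude=2e4)
        counts = forward_model(truth, irf, axis)
        fit = fit_biexponential(
            counts, irf, axis,
            init={"tau1_ps": 450.0, "tau2_ps": 1600.0, "alpha1": 0.6},
        )
        assert fit.params.alpha1 == pytest.approx(0.6, abs=1e-3)
        assert fit.params.tau1_ps == pytest.approx(450.0, rel=1e-3)

    def test_mono_exponential_input_recovers_alpha1_near_one(self, axis, irf):
        truth = DecayParams(
            tau1_ps=400.0, tau2_ps=1800.0, alpha1=1.0, amplitude=1e5
        )
        counts = simulate_decay(truth, irf, axis, rng=np.random.default_rng(0))
        fit = fit_biexponential(counts, irf, axis)
        assert fit.params.alpha1 >= 0.99

    def test_alpha1_estimator_bias_and_rmse_at_1e4_photons(self, axis, irf):
        """Estimator quality over 100 simulated decays at 1e4 photons."""
        rng = np.random.default_rng(12)
        truth = DecayParams(tau1_ps=400.0, tau2_ps=1800.0, alpha1=0.7, amplitude=1e4)
        est = []
        for _ in range(100):
            counts = simulate_decay(truth, irf, axis, rng=rng)
            est.append(fit_biexponential(counts, irf, axis).params.alpha1)
        est = np.array(est)
        assert abs(est.mean() - 0.7) < 0.02
        assert np.sqrt(np.mean((est - 0.7) ** 2)) < 0.05

    def test_too_few_photons_rejected(self, axis, irf):
        with pytest.raises(ValueError, match="photons"):
            fit_biexponential(np.ones(axis.n_bins), irf, axis)

    def test_tau_m_bounds_invariant(self, axis, irf):
        rng = np.random.default_rng(3)
        truth = DecayParams(tau1_ps=380.0, tau2_ps=1900.0, alpha1=0.75, amplitude=5e4)
        for _ in range(5):
            counts = simulate_decay(truth, irf, axis, rng=rng)
            fit = fit_biexponential(counts, irf, axis)
            assert (
                min(fit.params.tau1_ps, fit.params.tau2_ps)
                <= fit.tau_m_ps
                <= max(fit.params.tau1_ps, fit.params.tau2_ps)
            )


class TestMeanLifetime:
    def test_weighted_average_hand_value(self, axis, irf):
        p = DecayParams(tau1_ps=400.0, tau2_ps=1800.0, alpha1=0.79, amplitude=1e4)
        counts = forward_model(p, irf, axis)
        fit = fit_biexponential(counts, irf, axis)
        # 0.79*400 + 0.21*1800 = 694
        assert mean_lifetime(fit) == pytest.approx(694.0, rel=0.01)

    def test_monotone_decreasing_in_alpha1(self):
        taus = dict(tau1_ps=400.0, tau2_ps=1800.0, amplitude=1.0)
        tm = [DecayParams(alpha1=a, **taus).tau_m_ps for a in (0.0, 0.3, 0.8, 1.0)]
        assert tm == sorted(tm, reverse=True)
        assert tm[-1] == 400.0 and tm[0] == 1800.0


class TestCellLevelAnalysis:
    def test_glycolysis_cells_have_lower_tau_m(self, small_cells, irf):
        df = fit_cells(small_cells, irf)
        means = df.groupby("phenotype")["tau_m_ps"].mean()
        assert means["glycolysis"] < means["oxphos"]

    def test_alpha1_separates_glycolysis_from_oxphos(self, axis, irf):
        """Cell-mean alpha1 estimator separates the classes with AUC > 0.95."""
        from flimclass.evaluate import auc_trapezoid, roc_curve
        from flimclass.simulate import simulate_cell_dataset

        cells = simulate_cell_dataset(
            {"glycolysis": 50, "oxphos": 50}, axis, irf, rng=31,
            phenotypes=("glycolysis", "oxphos"),
        )
        df = fit_cells(cells, irf)
        is_gly = (df["phenotype"] == "glycolysis").to_numpy()
        fpr, tpr, _ = roc_curve(is_gly, df["alpha1"].to_numpy())
        assert auc_trapezoid(fpr, tpr) > 0.95


@pytest.fixture(scope="module")
def uniform_field(axis, irf):
    from flimclass.simulate import ClassPreset, simulate_field

    presets = {
        "oxphos": ClassPreset(
            "oxphos",
            DecayParams(tau1_ps=400.0, tau2_ps=1800.0, alpha1=0.68),
            cell_cv=0.0, pixel_cv=0.0, texture="diffuse",
        )
    }
    return simulate_field(
        2, {"oxphos": 2}, axis, irf, field_size=(48, 48), rng=8,
        photon_budget=800.0, presets=presets,
    )


class TestTauMImage:

    def test_uniform_field_gives_constant_tau_m(self, uniform_field, irf):
        taum, intensity = tau_m_image(uniform_field, irf)
        vals = taum[np.isfinite(taum)]
        assert vals.size > 0
        assert vals.std() < 0.05 * vals.mean()
        expected = 0.68 * 400.0 + 0.32 * 1800.0
        assert vals.mean() == pytest.approx(expected, rel=0.05)

    def test_background_is_missing_not_zero(self, uniform_field, irf):
        taum, _ = tau_m_image(uniform_field, irf)
        background = uniform_field.mask == 0
        assert np.isnan(taum[background]).all()


class TestAverageDecayCurve:
    def test_single_pixel_cell_is_unit_peak_decay(self, axis):
        counts = np.zeros((1, 1, axis.n_bins))
        counts[0, 0] = np.exp(-np.arange(axis.n_bins) / 30.0) * 50
        cell = fc.CellRecord(
            counts=counts, mask_crop=np.ones((1, 1), bool), time_axis=axis
        )
        curve = average_decay_curve([cell])
        np.testing.assert_allclose(curve, counts[0, 0] / counts[0, 0].max())

    def test_maximum_never_exceeds_one(self, small_cells):
        assert average_decay_curve(list(small_cells)).max() <= 1.0 + 1e-12
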