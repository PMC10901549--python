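import numpy as np
import pytest

import flimclass as fc
from flimclass.decaymodel import DecayParams
from flimclass.simulate import (
    CellGeometry,
    PlacementError,
    class_presets,
    random_geometry,
    simulate_cell,
    simulate_decay,
    simulate_field,
)


class TestDecayParams:
    def test_ordering_and_range_validation(self):
        with pytest.raises(ValueError):
            DecayParams(tau1_ps=2000.0, tau2_ps=400.0, alpha1=0.5)
        with pytest.raises(ValueError):
            DecayParams(tau1_ps=400.0, tau2_ps=1800.0, alpha1=1.2)

    def test_tau_m_is_weighted_average(self):
        p = DecayParams(tau1_ps=400.0, tau2_ps=1800.0, alpha1=0.79)
        assert p.tau_m_ps == pytest.approx(0.79 * 400 + 0.21 * 1800)


class TestSimulateDecay:
    def test_mono_exponential_limit_with_delta_irf(self):
        axis = fc.TimeAxis(64, 12.5)
        delta = np.zeros(64)
        delta[0] = 1.0
        p = DecayParams(tau1_ps=400.0, tau2_ps=1800.0, alpha1=1.0, amplitude=1e4)
        curve = simulate_decay(p, delta, axis, noiseless=True)
        t = axis.times_ps
        expected = np.exp(-t / 400.0)
        np.testing.assert_allclose(
            curve / curve[0], expected / expected[0], rtol=1e-9
        )

    def test_noiseless_peak_at_frame_64_or_65(self, axis, irf, presets):
        for preset in presets.values():
            curve = simulate_decay(preset.mean_params, irf, axis, noiseless=True)
            assert np.argmax(curve) + 1 in (64, 65)

    def test_photon_conservation_in_expectation(self, axis, irf):
        p = DecayParams(
            tau1_ps=400.0, tau2_ps=1800.0, alpha1=0.7, amplitude=1e5, offset=2.0
        )
        curve = simulate_decay(p, irf, axis, noiseless=True)
        expected_total = 1e5 + 2.0 * axis.n_bins
        assert curve.sum() == pytest.approx(expected_total, rel=1e-6)

    def test_noiseless_decay_non_increasing_after_peak(self, axis, irf, presets):
        curve = simulate_decay(
            presets["oxphos"].mean_params, irf, axis, noiseless=True
        )
        peak = np.argmax(curve)
        assert np.all(np.diff(curve[peak:]) <= 1e-12)

    def test_poisson_totals_concentrate_around_amplitude(self, axis, irf):
        p = DecayParams(tau1_ps=400.0, tau2_ps=1800.0, alpha1=0.7, amplitude=1e5)
        for seed in range(5):
            counts = simulate_decay(p, irf, axis, rng=np.random.default_rng(seed))
            assert abs(counts.sum() - 1e5) < 4 * np.sqrt(1e5)


class TestClassPresets:
    def test_fractions_match_measured_average_decays(self, presets):
        assert presets["glycolysis"].mean_params.alpha1 == 0.79
        assert presets["oxphos"].mean_params.alpha1 == 0.68
        assert presets["glutaminolysis"].mean_params.alpha1 == 0.68

    def test_lifetimes_within_free_and_bound_ranges(self, presets):
        assert set(presets) == {"glycolysis", "oxphos", "glutaminolysis"}
        for p in presets.values():
            assert 300 <= p.mean_params.tau1_ps <= 500
            assert 1500 <= p.mean_params.tau2_ps <= 2000

    def test_oxphos_and_glutaminolysis_carry_distinct_surrogate_cues(self, presets):
        ox, glu = presets["oxphos"], presets["glutaminolysis"]
        assert ox.texture != glu.texture
        assert glu.mean_params.tau2_ps != ox.mean_params.tau2_ps


class TestSimulateCell:
    def test_zero_photon_budget_gives_empty_stack(self, axis, irf, presets):
        geom = random_geometry(np.random.default_rng(0))
        rec = simulate_cell(
            presets["oxphos"], geom, axis, irf, photon_budget=0.0,
            rng=np.random.default_rng(1),
        )
        assert rec.counts.sum() == 0

    def test_pixels_outside_mask_are_zero(self, small_cells):
        rec = small_cells[0]
        assert rec.counts[~rec.mask_crop].sum() == 0

    def test_cytoplasm_to_nucleus_brightness_ratio(self, axis, irf, presets):
        geom = CellGeometry(
            center_xy=(0.0, 0.0), axes_px=(8.0, 7.0),
            nucleus_axes_px=(3.5, 3.0), intensity_ratio_nucleus=2.5,
        )
        rec = simulate_cell(
            presets["glycolysis"], geom, axis, irf, photon_budget=2000.0,
            rng=np.random.default_rng(2),
        )
        totals = rec.counts.sum(axis=2)
        nucleus = rec.truth["nucleus_mask"]
        cyto = rec.mask_crop & ~nucleus
        ratio = totals[cyto].mean() / totals[nucleus].mean()
        assert ratio == pytest.approx(2.5, rel=0.10)

    def test_same_seed_is_bit_identical(self, axis, irf, presets):
        geom = random_geometry(np.random.default_rng(3))
        a = simulate_cell(
            presets["oxphos"], geom, axis, irf, rng=np.random.default_rng(42)
        )
        b = simulate_cell(
            presets["oxphos"], geom, axis, irf, rng=np.random.default_rng(42)
        )
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_nucleus_must_fit_inside_cell(self):
        with pytest.raises(ValueError):
            CellGeometry(
                center_xy=(0, 0), axes_px=(5.0, 5.0), nucleus_axes_px=(6.0, 2.0)
            )


class TestSimulateField:
    def test_mask_has_requested_labels_and_mix(self, small_field):
        assert len(small_field.cell_ids) == 10
        from collections import Counter

        mix = Counter(small_field.labels.values())
        assert mix == {"glycolysis": 4, "oxphos": 3, "glutaminolysis": 3}

    def test_same_seed_reproduces_field(self, axis, irf):
        kwargs = dict(
            n_cells=4, class_mix={"glycolysis": 2, "oxphos": 2},
            axis=axis, irf_kernel=irf, field_size=(96, 96),
        )
        a = simulate_field(rng=9, **kwargs)
        b = simulate_field(rng=9, **kwargs)
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_impossible_placement_raises(self, axis, irf):
        with pytest.raises(PlacementError, match="cell"):
            simulate_field(
                8, {"oxphos": 8}, axis, irf, field_size=(24, 24),
                rng=0, max_attempts=5,
            )

    def test_glycolysis_average_decay_falls_faster_than_oxphos(self, small_field):
        from flimclass.fitting import average_decay_curve
        from flimclass.preprocess import extract_cells

        cells = extract_cells(small_field)
        by_class = {}
        for pheno in ("glycolysis", "oxphos"):
            group = [c for c in cells if c.phenotype == pheno]
            by_class[pheno] = average_decay_curve(group)
        axis = small_field.time_axis
        peak = int(np.argmax(by_class["oxphos"]))
        at_2ns = peak + int(round(2000.0 / axis.bin_width_ps))
        assert by_class["glycolysis"][at_2ns] < by_class["oxphos"][at_2ns]
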