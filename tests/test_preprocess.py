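import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flimclass as fc
from flimclass import preprocess as pp


def make_cell(counts, phenotype="oxphos", cell_id=1):
    counts = np.asarray(counts)
    return fc.CellRecord(
        counts=counts,
        mask_crop=np.ones(counts.shape[:2], bool),
        time_axis=fc.TimeAxis(counts.shape[2], 12.5),
        phenotype=phenotype,
        cell_id=cell_id,
    )


class TestExtractCells:
    def test_one_record_per_label_with_tight_bbox(self, small_field):
        recs = pp.extract_cells(small_field)
        assert len(recs) == 10
        for rec in recs:
            # bounding box is tight: every edge row/col touches the mask
            assert rec.mask_crop[0].any() and rec.mask_crop[-1].any()
            assert rec.mask_crop[:, 0].any() and rec.mask_crop[:, -1].any()

    def test_rectangular_cell_crop_shape(self):
        counts = np.zeros((20, 20, 8), dtype=np.int64)
        mask = np.zeros((20, 20), dtype=np.uint16)
        mask[3:8, 5:12] = 1  # 5 x 7 rectangle
        counts[3:8, 5:12] = 2
        fs = fc.FieldStack(
            counts=counts, mask=mask, labels={1: "oxphos"},
            time_axis=fc.TimeAxis(8, 12.5),
        )
        (rec,) = pp.extract_cells(fs)
        assert rec.counts.shape == (5, 7, 8)

    def test_photon_sum_preserved_and_neighbors_zeroed(self, small_field):
        recs = pp.extract_cells(small_field)
        for rec in recs:
            in_mask = small_field.counts[small_field.mask == rec.cell_id].sum()
            assert rec.counts.sum() == in_mask


class TestPeakFrame:
    def test_delta_decay(self):
        counts = np.zeros((2, 2, 32), int)
        counts[:, :, 9] = 5  # 1-based frame 10
        assert pp.peak_frame(make_cell(counts)) == 10

    def test_noiseless_cell_peaks_at_64_or_65(self, axis, irf, presets):
        from flimclass.simulate import random_geometry, simulate_cell

        rec = simulate_cell(
            presets["glycolysis"], random_geometry(np.random.default_rng(1)),
            axis, irf, rng=np.random.default_rng(1), noiseless=True,
        )
        assert pp.peak_frame(rec) in (64, 65)

    def test_matches_exhaustive_argmax(self, small_cells):
        for cell in small_cells[:5]:
            totals = [cell.counts[:, :, t].sum() for t in range(cell.n_frames)]
            brute = 1 + max(range(len(totals)), key=lambda t: totals[t])
            assert pp.peak_frame(cell) == brute

    def test_all_zero_cell_rejected(self):
        with pytest.raises(ValueError, match="photons"):
            pp.peak_frame(make_cell(np.zeros((2, 2, 8), int)))


class TestFrameEntropy:
    def test_constant_frame_is_zero_bits(self):
        assert pp.frame_entropy(np.full((8, 8), 7)) == 0.0
        assert pp.frame_entropy(np.zeros((8, 8))) == 0.0

    def test_two_equal_gray_levels_give_one_bit(self):
        frame = np.zeros((4, 4))
        frame[:2] = 10.0
        assert pp.frame_entropy(frame) == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        frame = rng.poisson(20.0, (6, 6))
        shuffled = rng.permutation(frame.ravel()).reshape(frame.shape)
        assert pp.frame_entropy(shuffled) == pytest.approx(
            pp.frame_entropy(frame)
        )


class TestEntropyFilter:
    def test_infinite_k_retains_all(self, small_cells):
        kept, qc = pp.entropy_filter(list(small_cells), k_sigma=np.inf)
        assert len(kept) == len(small_cells)
        assert qc["retained"].all()

    def test_near_empty_outlier_removed(self, axis, small_cells):
        degenerate = fc.CellRecord(
            counts=np.zeros((9, 9, axis.n_bins), int) + np.eye(9, dtype=int)[..., None],
            mask_crop=np.ones((9, 9), bool),
            time_axis=axis,
            phenotype="oxphos",
            cell_id=999,
        )
        cells = list(small_cells) + [degenerate]
        kept, qc = pp.entropy_filter(cells, k_sigma=2.0)
        row = qc.set_index("cell_id").loc[999]
        mu, sd = qc["entropy"].mean(), qc["entropy"].std(ddof=0)
        assert row["entropy"] < mu - 2 * sd  # verified outlier by construction
        assert not row["retained"]
        assert 999 not in [c.cell_id for c in kept]

    def test_retained_set_monotone_in_k_sigma(self, small_cells):
        sizes = [
            len(pp.entropy_filter(list(small_cells), k)[0])
            for k in (0.5, 1.0, 2.0, 4.0)
        ]
        assert sizes == sorted(sizes)


class TestStandardizeSpatial:
    def test_21x21_input_is_identity(self):
        counts = np.arange(21 * 21 * 4).reshape(21, 21, 4)
        out = pp.standardize_spatial(make_cell(counts))
        np.testing.assert_array_equal(out.counts, counts)

    def test_small_cell_padded_and_sum_preserved(self):
        counts = np.random.default_rng(0).poisson(5.0, (5, 7, 6))
        out = pp.standardize_spatial(make_cell(counts))
        assert out.counts.shape == (21, 21, 6)
        assert out.counts.sum() == counts.sum()
        assert out.counts.min() >= 0

    @pytest.mark.parametrize("shape", [(3, 3), (21, 21), (30, 12), (40, 40)])
    def test_output_spatial_shape_always_21(self, shape):
        counts = np.ones(shape + (4,), int)
        out = pp.standardize_spatial(make_cell(counts))
        assert out.counts.shape[:2] == (21, 21)
        assert out.counts.shape[2] == 4

    def test_oversized_cell_rejected_and_batch_skips(self):
        big = make_cell(np.ones((41, 10, 4), int))
        with pytest.raises(ValueError, match="exceeds"):
            pp.standardize_spatial(big)
        ok = make_cell(np.ones((10, 10, 4), int), cell_id=2)
        out = pp.standardize_cells([big, ok])
        assert [c.cell_id for c in out] == [2]


class TestDownsampleTime:
    def test_256_frames_become_128(self):
        stack = np.random.default_rng(1).poisson(4.0, (21, 21, 256))
        for method in ("mean", "median"):
            out = pp.downsample_time(stack, pp.DownsampleSpec(method))
            assert out.shape == (21, 21, 128)

    def test_constant_stack_unchanged(self):
        stack = np.full((4, 4, 64), 9)
        out = pp.downsample_time(stack, pp.DownsampleSpec("mean"))
        assert out.shape == (4, 4, 32)
        assert (out == 9).all()

    def test_median_is_identity_on_strictly_monotone_decay(self, axis):
        from flimclass.decaymodel import DecayParams, forward_model

        delta = np.zeros(axis.n_bins)
        delta[0] = 1.0  # delta IRF gives a strictly decreasing decay
        p = DecayParams(tau1_ps=400.0, tau2_ps=1800.0, alpha1=0.7, amplitude=1e6)
        curve = forward_model(p, delta, axis)
        assert (np.diff(curve) < 0).all()
        stack = curve[None, None, :]
        out = pp.downsample_time(stack, pp.DownsampleSpec("median"))
        # brute-force per-frame: interior odd frames of a locally monotone
        # signal are fixed points of the window-3 median
        for j in range(1, out.shape[2] - 1):
            t = 2 * j  # 0-based original index of 1-based odd frame 2j+1
            triple = sorted(curve[t - 1 : t + 2])
            assert out[0, 0, j] == pytest.approx(triple[1])
            assert out[0, 0, j] == pytest.approx(curve[t])

    @given(st.integers(3, 300), st.sampled_from(["mean", "median"]))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_output_length_is_ceil_half(self, T, method):
        stack = np.ones((2, 2, T), int)
        out = pp.downsample_time(stack, pp.DownsampleSpec(method))
        assert out.shape[2] == -(-T // 2)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            pp.DownsampleSpec("mean", window=2)

    def test_peak_moves_to_about_half(self, axis, irf, presets):
        from flimclass.simulate import random_geometry, simulate_cell

        rec = simulate_cell(
            presets["oxphos"], random_geometry(np.random.default_rng(2)),
            axis, irf, rng=np.random.default_rng(2), noiseless=True,
        )
        peak = pp.peak_frame(rec)
        down = rec.with_counts(
            pp.downsample_time(rec.counts, pp.DownsampleSpec("mean")),
            time_axis=fc.TimeAxis(128, axis.window_ns),
        )
        assert abs(pp.peak_frame(down) - (-(-peak // 2))) <= 1


class TestTemporalFeatures:
    def test_length_equals_frames(self, small_cells):
        cell = small_cells[0]
        feats = pp.temporal_features(cell)
        assert feats.shape == (cell.n_frames,)

    def test_single_pixel_cell_features_equal_decay(self):
        counts = np.arange(16)[None, None, :]
        cell = make_cell(counts)
        np.testing.assert_array_equal(pp.temporal_features(cell), counts[0, 0])

    def test_linearity_in_counts(self, small_cells):
        cell = small_cells[1]
        tripled = cell.with_counts(cell.counts * 3)
        np.testing.assert_allclose(
            pp.temporal_features(tripled), 3 * pp.temporal_features(cell)
        )


@pytest.fixture(scope="module")
def cells100():
    rng = np.random.default_rng(5)
    phenos = ["glycolysis"] * 40 + ["oxphos"] * 30 + ["glutaminolysis"] * 30
    return [
        fc.CellRecord(
            counts=rng.poisson(2.0, (3, 3, 8)) + 1,
            mask_crop=np.ones((3, 3), bool),
            time_axis=fc.TimeAxis(8, 12.5),
            phenotype=p,
            cell_id=i + 1,
        )
        for i, p in enumerate(phenos)
    ]


class TestBuildDataset:

    def test_split_counts(self, cells100):
        b = pp.build_dataset(cells100, seed=3)
        tags, counts = np.unique(b.split, return_counts=True)
        assert dict(zip(tags, counts)) == {"train": 70, "val": 10, "test": 20}

    def test_folds_partition_cells(self, cells100):
        b = pp.build_dataset(cells100, seed=3)
        assert set(b.fold) == set(range(5))
        assert len(b.fold) == 100  # exhaustive, disjoint by construction

    def test_folds_stratified_within_one_cell(self, cells100):
        import pandas as pd

        b = pp.build_dataset(cells100, seed=3)
        df = pd.DataFrame(
            {"fold": b.fold, "pheno": [c.phenotype for c in b.cells]}
        )
        table = df.value_counts(["fold", "pheno"]).unstack()
        for pheno, total in {"glycolysis": 40, "oxphos": 30, "glutaminolysis": 30}.items():
            expected = total / 5
            assert (abs(table[pheno] - expected) <= 1).all()

    def test_class_smaller_than_folds_rejected(self, cells100):
        with pytest.raises(ValueError, match="fold"):
            pp.build_dataset(cells100[:42], folds=5, seed=0)  # 2 glutaminolysis
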