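import numpy as np
import pytest

import arraybench as ab
from arraybench.containers import SpotTable
from arraybench.normalization import (background_correct, compute_MA,
                                      loess_normalize, normalize_dataset)


def make_spots(R_fg, R_bg=None, G_fg=None, G_bg=None, block=None, flag=None):
    n = len(R_fg)
    zeros = np.zeros(n)
    return SpotTable(
        gene_id=np.array([f"g{i}" for i in range(n)], dtype=object),
        block=np.asarray(block) if block is not None else np.ones(n, dtype=int),
        R_fg=np.asarray(R_fg, dtype=float),
        R_bg=np.asarray(R_bg, dtype=float) if R_bg is not None else zeros.copy(),
        G_fg=np.asarray(G_fg, dtype=float) if G_fg is not None else
        np.asarray(R_fg, dtype=float),
        G_bg=np.asarray(G_bg, dtype=float) if G_bg is not None else zeros.copy(),
        flag=np.asarray(flag, dtype=bool) if flag is not None else
        np.zeros(n, dtype=bool),
    )


class TestBackgroundCorrect:
    def test_subtracts_local_background(self):
        s = make_spots([500.0], R_bg=[100.0], G_fg=[300.0], G_bg=[50.0])
        out = background_correct(s)
        assert out.R_fg[0] == 400.0 and out.G_fg[0] == 250.0

    def test_signal_below_background_becomes_missing(self):
        s = make_spots([500.0], R_bg=[100.0], G_fg=[100.0], G_bg=[150.0])
        out = background_correct(s)
        assert np.isnan(out.R_fg[0]) and np.isnan(out.G_fg[0])

    def test_zero_background_is_identity(self):
        s = make_spots([500.0, 20.0], G_fg=[30.0, 40.0])
        out = background_correct(s)
        np.testing.assert_array_equal(out.R_fg, s.R_fg)
        np.testing.assert_array_equal(out.G_fg, s.G_fg)


class TestComputeMA:
    def test_equal_channels_give_zero_m(self):
        M, A = compute_MA(make_spots([200.0], G_fg=[200.0]))
        assert M[0] == 0.0

    def test_closed_form_values(self):
        M, A = compute_MA(make_spots([800.0], G_fg=[200.0]))
        assert M[0] == pytest.approx(2.0)
        assert A[0] == pytest.approx(8.6439, abs=1e-4)

    def test_missing_and_nonpositive_propagate(self):
        M, A = compute_MA(make_spots([np.nan, 0.0, 100.0],
                                     G_fg=[100.0, 100.0, -5.0]))
        assert np.isnan(M).all() and np.isnan(A).all()


class TestLoessNormalize:
    def test_constant_m_maps_to_zero(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(6, 14, 500)
        M = np.full(500, 1.7)
        out = loess_normalize(M, A)
        assert np.max(np.abs(out)) < 1e-6

    def test_removes_smooth_intensity_bias(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(6, 14, 2000)
        noise_sd = 0.3
        bias = 0.8 * np.sin((A - 6) / 8 * np.pi) + 0.1 * (A - 10)
        M = bias + rng.normal(0, noise_sd, 2000)
        out = loess_normalize(M, A)
        assert np.mean(np.abs(out)) < noise_sd
        # a second smoother on the normalized data finds no structure left
        assert np.max(np.abs(out - loess_normalize(out, A))) < 0.05

    def test_grouped_fit_removes_per_block_offsets(self):
        rng = np.random.default_rng(2)
        n_blocks, per = 4, 400
        A = rng.uniform(6, 14, n_blocks * per)
        groups = np.repeat(np.arange(1, n_blocks + 1), per)
        offsets = np.array([-0.8, 0.3, 0.5, -0.2])
        M = offsets[groups - 1] + rng.normal(0, 0.1, n_blocks * per)
        out = loess_normalize(M, A, groups=groups)
        for b in range(1, n_blocks + 1):
            assert abs(out[groups == b].mean()) < 0.02

    def test_missing_entries_pass_through(self):
        rng = np.random.default_rng(3)
        A = rng.uniform(6, 14, 200)
        M = rng.normal(0, 1, 200)
        M[5] = np.nan
        out = loess_normalize(M, A)
        assert np.isnan(out[5]) and np.isfinite(np.delete(out, 5)).all()

    def test_tiny_group_falls_back_to_median(self):
        M = np.array([1.0, 2.0, 3.0])
        out = loess_normalize(M, np.array([7.0, 8.0, 9.0]))
        np.testing.assert_allclose(out, M - 2.0)

    def test_idempotent_in_expectation_on_generated_arrays(self):
        cfg = ab.SimConfig(n_samples=4, n_patients=4, seed=9)
        spots, _ = ab.generate_dataset(cfg)
        for s in spots:
            M, A = compute_MA(s)
            once = loess_normalize(M, A)
            twice = loess_normalize(once, A)
            assert np.nanmean(np.abs(twice - once)) < 0.01


class TestNormalizeDataset:
    def test_raw_equals_compute_ma_exactly(self, clean_dataset):
        spots, meta, _ = clean_dataset
        matrix = normalize_dataset(spots, meta, 0)
        for j, s in enumerate(spots):
            M, _ = compute_MA(s)
            np.testing.assert_array_equal(matrix.values[:, j], M)

    def test_shape_and_order_preserved(self, clean_dataset):
        spots, meta, _ = clean_dataset
        for method in (0, 1, 3):
            m = normalize_dataset(spots, meta, method)
            assert m.values.shape == (spots[0].n_spots, len(meta))
            assert m.gene_ids == list(spots[0].gene_id)
            assert [x.sample_id for x in m.meta] == [x.sample_id for x in meta]

    def test_bias_free_raw_close_to_global_loess(self):
        # at zero dye bias the loess fit tracks only noise wiggle, which
        # scales with the spot noise; moderate noise keeps it visible
        cfg = ab.SimConfig(n_genes=2000, n_samples=6, n_patients=6, n_diff=0,
                           effect_size=0.0, noise_sd=0.1,
                           dye_bias_amplitude=0.0, background_level=0.0,
                           flag_rate=0.0, dup_rate=0.0, seed=8)
        spots, meta = ab.generate_dataset(cfg)
        raw = normalize_dataset(spots, meta, 0)
        glo = normalize_dataset(spots, meta, 3)
        diff = np.abs(raw.values - glo.values)
        assert np.nanmax(diff) < 0.05

    def test_printtip_loess_beats_global_on_block_offsets(self):
        cfg = ab.SimConfig(n_genes=800, n_samples=10, n_patients=10, n_diff=0,
                           effect_size=0.0, noise_sd=0.3,
                           dye_bias_amplitude=1.0, n_printtips=8,
                           background_level=0.0, flag_rate=0.0, dup_rate=0.0,
                           seed=5)
        spots, meta = ab.generate_dataset(cfg)
        tip = normalize_dataset(spots, meta, 1)
        glo = normalize_dataset(spots, meta, 3)
        blocks = spots[0].block
        def block_mean_abs(m):
            return np.mean([abs(np.nanmean(m.values[blocks == b, j]))
                            for b in range(1, 9) for j in range(10)])
        assert block_mean_abs(tip) < block_mean_abs(glo)

    def test_background_correction_adds_missing(self):
        cfg = ab.SimConfig(n_genes=500, n_samples=6, n_patients=6, n_diff=0,
                           effect_size=0.0, background_level=500.0,
                           flag_rate=0.0, dup_rate=0.0, seed=6)
        spots, meta = ab.generate_dataset(cfg)
        no1 = normalize_dataset(spots, meta, 1)
        no2 = normalize_dataset(spots, meta, 2)
        m1, m2 = no1.missing_mask, no2.missing_mask
        assert (m2 & ~m1).any()
        assert not (m1 & ~m2).any()

    def test_printtip_requires_blocks(self):
        cfg = ab.SimConfig(n_genes=100, n_samples=4, n_patients=4, n_diff=0,
                           n_printtips=1, seed=0)
        spots, meta = ab.generate_dataset(cfg)
        with pytest.raises(ValueError, match="print-tip"):
            normalize_dataset(spots, meta, 1)

    def test_unknown_method_rejected(self, clean_dataset):
        spots, meta, _ = clean_dataset
        with pytest.raises(ValueError):
            normalize_dataset(spots, meta, 9)
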