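"""Masked Pearson correlation maps vs a dense brute-force oracle."""

import numpy as np
import pytest

import hicpat as hp
from hicpat.correlate import correlation_map, correlation_map_tsvd

from conftest import masked_pearson_oracle


def random_fixture(seed, n=60, density=0.3, kshape=(9, 9), n_masked=3):
    rng = np.random.default_rng(seed)
    img = rng.lognormal(0.0, 0.8, (n, n)) * (rng.random((n, n)) < density)
    img = np.triu(img) + np.triu(img, 1).T  # symmetric
    kern = hp.Kernel("rnd", rng.random(kshape) + 0.1 * np.eye(*kshape))
    valid = np.ones(n, dtype=bool)
    valid[rng.choice(n, size=n_masked, replace=False)] = False
    return img, kern, valid


def oracle_of(img, kern, valid_rows, valid_cols, max_empty_fraction=0.3):
    k = kern.standardised()
    vmask = np.outer(valid_rows, valid_cols)
    min_valid = int(np.ceil((1 - max_empty_fraction) * k.matrix.size))
    return masked_pearson_oracle(img, vmask, k.matrix, min_valid)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_full_scan_matches_dense_oracle(self, seed):
        img, kern, valid = random_fixture(seed)
        cmap = correlation_map(img, kern, valid_rows=valid, valid_cols=valid, intra=False)
        got = cmap.dense()
        scores, defined = oracle_of(img, kern, valid, valid)
        assert np.array_equal(~np.isnan(got), defined)
        assert np.nanmax(np.abs(got - scores)) < 1e-10 if defined.any() else True

    @pytest.mark.parametrize("seed", range(8, 14))
    def test_banded_scan_matches_oracle_on_band(self, seed):
        img, kern, valid = random_fixture(seed, n=80)
        lo_d, hi_d = 6, 40
        cmap = correlation_map(img, kern, valid_rows=valid,
                               min_dist_bins=lo_d, max_dist_bins=hi_d)
        got = cmap.dense()
        scores, defined = oracle_of(img, kern, valid, valid)
        i, j = np.indices(img.shape)
        band = (j - i >= lo_d) & (j - i <= hi_d)
        assert np.array_equal(~np.isnan(got), defined & band)
        sel = defined & band
        if sel.any():
            assert np.max(np.abs(got[sel] - scores[sel])) < 1e-10

    def test_tiled_scan_equals_single_tile(self):
        img, kern, valid = random_fixture(99, n=100)
        a = correlation_map(img, kern, valid_rows=valid, max_dist_bins=50)
        b = correlation_map(img, kern, valid_rows=valid, max_dist_bins=50,
                            tile_rows=17)
        assert np.array_equal(a.rows, b.rows)
        assert np.array_equal(a.cols, b.cols)
        assert np.array_equal(a.scores, b.scores)


class TestPointwiseContracts:
    def test_affine_window_scores_one(self, loops_kernel):
        k = loops_kernel.standardised()
        n = 41
        img = np.zeros((n, n))
        img[20 - 8:20 + 9, 20 - 8:20 + 9] = 3.0 * k.matrix + 7.0
        cmap = correlation_map(img, k, intra=False)
        got = cmap.dense()
        assert got[20, 20] == pytest.approx(1.0, abs=1e-12)

    def test_constant_window_masked_not_zero(self, loops_kernel):
        img = np.full((31, 31), 2.0)
        cmap = correlation_map(img, loops_kernel, intra=False)
        assert cmap.n_scored == 0

    def test_edge_windows_not_scored(self, loops_kernel):
        img = np.random.default_rng(0).random((40, 40))
        cmap = correlation_map(img, loops_kernel, intra=False)
        assert cmap.rows.min() >= 8 and cmap.rows.max() < 32

    def test_kernel_larger_than_block_rejected(self, loops_kernel):
        with pytest.raises(ValueError, match="larger"):
            correlation_map(np.ones((10, 10)), loops_kernel, intra=False)


class TestInvariants:
    def test_coefficients_bounded(self):
        for seed in range(3):
            img, kern, valid = random_fixture(seed, n=50)
            cmap = correlation_map(img, kern, valid_rows=valid, valid_cols=valid, intra=False)
            if cmap.n_scored:
                assert np.all(np.abs(cmap.scores) <= 1.0)

    def test_symmetric_kernel_symmetric_map(self):
        rng = np.random.default_rng(5)
        img = rng.random((50, 50))
        img = (img + img.T) / 2
        km = rng.random((7, 7))
        kern = hp.Kernel("symk", (km + km.T) / 2)
        cmap = correlation_map(img, kern, intra=False)
        dense = cmap.dense()
        sel = ~np.isnan(dense) & ~np.isnan(dense.T)
        assert np.allclose(dense[sel], dense.T[sel], atol=1e-10)

    def test_mask_monotonicity(self):
        img, kern, valid = random_fixture(21, n=50)
        base = correlation_map(img, kern, valid_rows=valid, valid_cols=valid, intra=False)
        more = valid.copy()
        more[[10, 25]] = False
        shrunk = correlation_map(img, kern, valid_rows=more, valid_cols=more, intra=False)
        base_set = set(zip(base.rows.tolist(), base.cols.tolist()))
        shrunk_set = set(zip(shrunk.rows.tolist(), shrunk.cols.tolist()))
        assert shrunk_set <= base_set


class TestTSVDPath:
    def test_full_rank_matches_exact_path(self):
        img, kern, valid = random_fixture(31, n=60)
        exact = correlation_map(img, kern, valid_rows=valid, valid_cols=valid, intra=False)
        approx = correlation_map_tsvd(img, kern, rank=9, valid_rows=valid,
                                      valid_cols=valid, intra=False)
        assert np.array_equal(exact.rows, approx.rows)
        assert np.max(np.abs(exact.scores - approx.scores)) < 1e-8

    def test_rank_one_exact_for_separable_kernel(self):
        rng = np.random.default_rng(7)
        img = rng.random((40, 40))
        kern = hp.Kernel("sep", np.outer(rng.random(7) + 0.5,
                                         rng.random(7) + 0.5))
        exact = correlation_map(img, kern, intra=False)
        approx = correlation_map_tsvd(img, kern, rank=1, intra=False)
        assert np.max(np.abs(exact.scores - approx.scores)) < 1e-8

    def test_low_rank_recovers_detections(self, sim_matrix, loops_kernel):
        m, _ = sim_matrix
        exact = hp.detect(m, loops_kernel, pearson=0.35)
        approx = hp.detect(m, loops_kernel, pearson=0.35, tsvd_rank=3)
        e = {(d.bin1, d.bin2) for d in exact}
        a = {(d.bin1, d.bin2) for d in approx}
        # rank-3 template keeps nearly all above-threshold sites
        assert len(e & a) >= 0.9 * max(len(e), 1)
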