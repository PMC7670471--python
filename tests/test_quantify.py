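"""Quantification of fixed coordinates, pileups and loop spectra."""

import numpy as np
import pytest

import hicpat as hp

from conftest import planted_kernel_matrix, toy_matrix


def noise_matrix(n=160, seed=0):
    """Detrended-style i.i.d. noise map (mean 1) with no structure."""
    rng = np.random.default_rng(seed)
    dense = rng.lognormal(-0.125, 0.5, (n, n))
    dense = (dense + dense.T) / 2
    return toy_matrix(dense, is_balanced=True, is_detrended=True)


class TestQuantify:
    def test_reproduces_detect_scores_exactly(self, sim_matrix, loops_kernel):
        m, _ = sim_matrix
        dets = hp.detect(m, loops_kernel, pearson=0.3)
        assert len(dets) > 0
        res = hp.quantify(m, [(d.bin1, d.bin2) for d in dets], loops_kernel)
        for d, q in zip(dets, res):
            assert q.ok
            assert q.score == d.score  # bit-for-bit

    def test_planted_copy_scores_one(self, loops_kernel):
        m = planted_kernel_matrix(loops_kernel, at=(40, 90))
        res = hp.quantify(m, [(40, 90)], loops_kernel)
        assert res[0].score == pytest.approx(1.0, abs=1e-12)

    def test_noise_scores_centre_on_zero(self, loops_kernel):
        m = noise_matrix(seed=1)
        rng = np.random.default_rng(2)
        coords = [(int(i), int(j)) for i, j in
                  zip(rng.integers(10, 150, 200), rng.integers(10, 150, 200))
                  if j - i > 12]
        res = hp.quantify(m, coords, loops_kernel)
        scores = np.array([r.score for r in res if r.ok])
        se = scores.std(ddof=1) / np.sqrt(scores.size)
        assert abs(scores.mean()) < 3 * se

    def test_edge_and_invalid_coordinates_flagged(self, loops_kernel):
        m = noise_matrix(n=60)
        res = hp.quantify(m, [(0, 3), (30, 40)], loops_kernel)
        assert res[0].status == "edge" and np.isnan(res[0].score)
        assert res[1].ok
        coord = hp.Coordinate2D("chrX", 0, 2000, "chrX", 8000, 10000)
        res = hp.quantify(m, [coord], loops_kernel)
        assert res[0].status == "out-of-range"

    def test_masked_centre_flagged(self, loops_kernel):
        m = noise_matrix(n=80)
        m.valid_bins[40] = False
        res = hp.quantify(m, [(40, 60)], loops_kernel)
        assert res[0].status == "masked"


class TestPileup:
    def test_radius8_gives_17x17(self, sim_matrix):
        m, truth = sim_matrix
        mean, used = hp.pileup(m, truth.loops, window_radius_bins=8)
        assert mean.shape == (17, 17)
        assert used > 0

    def test_single_coordinate_equals_window(self, loops_kernel):
        m = noise_matrix(n=60, seed=5)
        mean, used = hp.pileup(m, [(20, 40)], window_radius_bins=4)
        assert used == 1
        block = m.block("chr1", dense=True)
        assert np.allclose(mean, block[16:25, 36:45], atol=1e-15)

    def test_order_invariance(self, sim_matrix):
        m, truth = sim_matrix
        a, _ = hp.pileup(m, truth.loops)
        b, _ = hp.pileup(m, truth.loops[::-1])
        assert np.array_equal(a, b)

    def test_planted_windows_average_to_template(self, loops_kernel):
        # several shifted exact copies -> pileup correlates 1.0 with template
        k = loops_kernel.standardised()
        n, h = 200, 8
        dense = np.zeros((n, n))
        spots = [(30, 80), (60, 120), (100, 170), (25, 160)]
        for r, c in spots:
            dense[r - h:r + h + 1, c - h:c + h + 1] = 2.0 * k.matrix + 5.0
        m = toy_matrix(dense, is_balanced=True, is_detrended=True)
        mean, used = hp.pileup(m, spots, window_radius_bins=8)
        assert used == len(spots)
        corr = np.corrcoef(mean.ravel(), k.matrix.ravel())[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-12)

    def test_no_usable_window_raises(self, loops_kernel):
        m = noise_matrix(n=40)
        with pytest.raises(ValueError, match="no usable window"):
            hp.pileup(m, [(0, 1)], window_radius_bins=8)


class TestLoopSpectrum:
    def test_peak_at_planted_spacing(self, loops_kernel):
        cfg = hp.SimConfig(seed=202, border_spacing_sd=0.0,
                           border_spacing_mean=20.0, loop_min_dist=18,
                           loop_max_dist=22, loop_probability=1.0)
        data, _ = hp.simulate_dataset(cfg, n_matrices=1)
        m, truth = data[0]
        anchors = [("chrS", b * 2000 + 1000) for b in truth.borders]
        spec = hp.loop_spectrum(m, anchors, loops_kernel,
                                max_dist_bp=130 * 2000, bucket_width_bins=2,
                                seed=0)
        peak = spec.loc[spec["mean_score"].idxmax()]
        planted_bucket = (20 // 2)
        peak_bucket = int(peak.distance_bp / 2000) // 2
        assert abs(peak_bucket - planted_bucket) <= 1

    def test_flat_on_structureless_map(self, loops_kernel):
        m = noise_matrix(n=220, seed=9)
        anchors = [("chr1", int(p) * 2000) for p in range(15, 205, 12)]
        spec = hp.loop_spectrum(m, anchors, loops_kernel,
                                max_dist_bp=80 * 2000, seed=3)
        pooled = spec["mean_score"].mean()
        for _, row in spec.iterrows():
            if row["n"] > 1 and row["ci_defined"]:
                se = (row["ci_hi"] - row["ci_lo"]) / (2 * 1.96)
                assert abs(row["mean_score"] - pooled) < max(3 * se, 0.05)

    def test_single_pair_ci_flagged(self, loops_kernel):
        m = noise_matrix(n=80, seed=4)
        anchors = [("chr1", 30 * 2000), ("chr1", 50 * 2000)]
        spec = hp.loop_spectrum(m, anchors, loops_kernel,
                                max_dist_bp=60 * 2000)
        assert len(spec) == 1
        assert not spec.iloc[0]["ci_defined"]
        assert np.isnan(spec.iloc[0]["ci_lo"])

    def test_smoothing_leaves_table_columns(self, sim_matrix, loops_kernel):
        m, truth = sim_matrix
        anchors = [("chrS", b * 2000) for b in truth.borders]
        spec = hp.loop_spectrum(m, anchors, loops_kernel,
                                max_dist_bp=100 * 2000)
        sm = hp.smooth_spectrum(spec)
        assert "smoothed_score" in sm.columns
        assert np.array_equal(sm["mean_score"].to_numpy(),
                              spec["mean_score"].to_numpy())
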