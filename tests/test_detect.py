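"""Focus labelling, greedy filtering and the end-to-end detector."""

import numpy as np
import pytest

import hicpat as hp
from hicpat.correlate import CorrelationMap
from hicpat.detect import filter_detections, label_foci

from conftest import flood_fill_components, planted_kernel_matrix, toy_matrix


def cmap_from_dense(arr: np.ndarray) -> CorrelationMap:
    rows, cols = np.nonzero(~np.isnan(arr))
    return CorrelationMap(shape=arr.shape, rows=rows, cols=cols,
                          scores=arr[rows, cols])


class TestLabelFoci:
    def test_single_pixel_focus_discarded(self):
        arr = np.full((10, 10), np.nan)
        arr[4, 7] = 0.9
        assert label_foci(cmap_from_dense(arr), tau=0.5) == []

    def test_diagonal_adjacency_does_not_connect(self):
        arr = np.full((10, 10), np.nan)
        arr[3, 3] = 0.9
        arr[4, 4] = 0.8  # touches only diagonally -> two size-1 components
        assert label_foci(cmap_from_dense(arr), tau=0.5) == []

    def test_two_adjacent_pixels_form_one_focus(self):
        arr = np.full((10, 10), np.nan)
        arr[3, 3], arr[3, 4] = 0.7, 0.9
        foci = label_foci(cmap_from_dense(arr), tau=0.5)
        assert len(foci) == 1
        assert foci[0].argmax == (3, 4, 0.9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        arr = np.where(rng.random((25, 25)) < 0.35, 0.8, np.nan)
        foci = label_foci(cmap_from_dense(arr), tau=0.5, min_size=1)
        got = {frozenset(zip(f.rows.tolist(), f.cols.tolist())) for f in foci}
        expect = {frozenset(c) for c in flood_fill_components(~np.isnan(arr))}
        assert got == expect

    def test_argmax_tie_breaks_lexicographically(self):
        arr = np.full((6, 6), np.nan)
        arr[2, 2] = arr[2, 3] = arr[3, 2] = 0.8
        foci = label_foci(cmap_from_dense(arr), tau=0.5)
        assert foci[0].argmax == (2, 2, 0.8)


class TestFilterDetections:
    def _foci(self, peaks):
        out = []
        for (r, c, s) in peaks:
            out.append(hp.Focus(rows=np.array([r, r]), cols=np.array([c, c + 1]),
                                scores=np.array([s, s - 0.05])))
        return out

    def test_close_pair_keeps_higher_score(self):
        foci = self._foci([(10, 20, 0.9), (12, 22, 0.8)])  # 3 bins apart? -> 2,2
        dets = filter_detections(foci, min_separation_bins=5)
        assert [(d.bin1, d.bin2, d.score) for d in dets] == [(10, 20, 0.9)]

    def test_distance_at_threshold_survives(self):
        foci = self._foci([(10, 20, 0.9), (15, 20, 0.8)])
        dets = filter_detections(foci, min_separation_bins=5)
        assert len(dets) == 2

    def test_equal_scores_far_apart_deterministic_order(self):
        foci = self._foci([(30, 60, 0.8), (10, 20, 0.8)])
        dets = filter_detections(foci, min_separation_bins=5)
        assert [(d.bin1, d.bin2) for d in dets] == [(10, 20), (30, 60)]

    def test_poorly_covered_window_discarded(self):
        valid = np.ones(40, dtype=bool)
        valid[18:25] = False  # blanket the window of the stronger peak
        foci = self._foci([(20, 30, 0.9), (5, 32, 0.7)])
        dets = filter_detections(foci, min_separation_bins=3,
                                 kernel_shape=(7, 7), valid_rows=valid,
                                 max_empty_fraction=0.3)
        assert [(d.bin1, d.bin2) for d in dets] == [(5, 32)]

    def test_greedy_is_maximal_independent_set(self):
        rng = np.random.default_rng(3)
        peaks = [(int(r), int(c), float(s)) for r, c, s in
                 zip(rng.integers(0, 30, 15), rng.integers(0, 30, 15),
                     rng.random(15))]
        dets = filter_detections(self._foci(peaks), min_separation_bins=4)
        pts = [(d.bin1, d.bin2) for d in dets]
        # pairwise separated
        for a in range(len(pts)):
            for b in range(a + 1, len(pts)):
                assert max(abs(pts[a][0] - pts[b][0]),
                           abs(pts[a][1] - pts[b][1])) >= 4
        # maximal: every rejected candidate is blocked by an accepted one
        for (r, c, s) in peaks:
            if (r, c) not in pts:
                assert any(max(abs(r - p), abs(c - q)) < 4 for p, q in pts)


class TestDetectEndToEnd:
    def test_all_zero_matrix_yields_nothing(self, loops_kernel):
        m = toy_matrix(np.zeros((60, 60)), is_balanced=True, is_detrended=True)
        assert hp.detect(m, loops_kernel) == []

    def test_planted_copy_single_exact_detection(self, loops_kernel):
        m = planted_kernel_matrix(loops_kernel, n=120, at=(40, 90))
        dets = hp.detect(m, loops_kernel, pearson=0.5)
        assert len(dets) == 1
        d = dets[0]
        assert (d.bin1, d.bin2) == (40, 90)
        assert d.score == pytest.approx(1.0, abs=1e-12)
        assert d.coord.chrom1 == "chr1" and d.coord.start1 == 40 * 2000

    def test_threshold_monotonicity(self, sim_matrix, loops_kernel):
        m, _ = sim_matrix
        lo = {(d.bin1, d.bin2) for d in hp.detect(m, loops_kernel, pearson=0.3)}
        hi = {(d.bin1, d.bin2) for d in hp.detect(m, loops_kernel, pearson=0.45)}
        assert hi <= lo

    def test_detections_respect_min_separation(self, sim_matrix, loops_kernel):
        m, _ = sim_matrix
        dets = hp.detect(m, loops_kernel, pearson=0.3, min_separation_bins=5)
        pts = [(d.bin1, d.bin2) for d in dets]
        for a in range(len(pts)):
            for b in range(a + 1, len(pts)):
                assert max(abs(pts[a][0] - pts[b][0]),
                           abs(pts[a][1] - pts[b][1])) >= 5

    def test_determinism(self, sim_matrix, loops_kernel):
        m, _ = sim_matrix
        d1 = hp.detect(m, loops_kernel)
        d2 = hp.detect(m, loops_kernel)
        assert [(d.bin1, d.bin2, d.score) for d in d1] == \
            [(d.bin1, d.bin2, d.score) for d in d2]

    def test_scores_never_below_threshold(self, sim_matrix, loops_kernel):
        m, _ = sim_matrix
        dets = hp.detect(m, loops_kernel, pearson=0.4)
        assert all(d.score >= 0.4 for d in dets)

    def test_recovers_most_planted_loops(self, small_dataset, loops_kernel):
        matchings = []
        for m, truth in small_dataset:
            dets = hp.detect(m, loops_kernel, pearson=0.25)
            matchings.append(hp.match_detections(dets, truth.loops, 2))
        met = hp.pooled_prf1(matchings)
        assert met.sensitivity >= 0.6
        assert met.precision >= 0.6
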