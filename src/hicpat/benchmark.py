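"""Score detections against ground truth: matching, precision/recall/F1,
and parameter-grid sweeps over labelled synthetic datasets.

Matching is one-to-one and greedy by increasing Chebyshev distance: a
detection within the tolerance of a still-unmatched truth point becomes a
true positive; leftover detections are false positives and leftover truth
points false negatives.  Metrics over an ensemble of matrices are pooled
(micro-averaged) from the summed TP/FP/FN counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .correlate import correlation_map
from .detect import Detection, _prepare, filter_detections, label_foci
from .kernels import Kernel

__all__ = ["Matching", "PRF1", "match_detections", "prf1", "pooled_prf1",
           "parameter_sweep"]


@dataclass
class Matching:
    """One-to-one matching between detections and truth points."""

    tp: list[tuple[tuple[int, int], tuple[int, int]]]  # (detection, truth)
    fp: list[tuple[int, int]]
    fn: list[tuple[int, int]]

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.tp), len(self.fp), len(self.fn)


@dataclass
class PRF1:
    precision: float
    sensitivity: float
    f1: float
    tp: int
    fp: int
    fn: int
    precision_defined: bool = True
    sensitivity_defined: bool = True


def _as_pairs(items) -> list[tuple[int, int]]:
    out = []
    for it in items:
        if isinstance(it, Detection):
            out.append((it.bin1, it.bin2))
        else:
            out.append((int(it[0]), int(it[1])))
    return out


def match_detections(detections, truth, tolerance_bins: int = 2) -> Matching:
    """One-to-one maximum-cardinality matching within the tolerance.

    Detections and truth points form a bipartite graph with an edge wherever
    their Chebyshev distance is at most ``tolerance_bins``.  Detections are
    processed in input order and each prefers closer truth points; an
    augmenting-path search (Kuhn's algorithm) then guarantees the matching
    has maximum cardinality, so the TP count never depends on a fortunate
    scan order.  The result is deterministic for fixed inputs.
    """
    dets = _as_pairs(detections)
    true = _as_pairs(truth)
    adj: list[list[int]] = []
    for (r, c) in dets:
        near = []
        for ti, (tr, tc) in enumerate(true):
            dist = max(abs(r - tr), abs(c - tc))
            if dist <= tolerance_bins:
                near.append((dist, ti))
        near.sort()
        adj.append([ti for _, ti in near])

    match_t: dict[int, int] = {}  # truth -> detection

    def augment(di: int, seen: set[int]) -> bool:
        for ti in adj[di]:
            if ti in seen:
                continue
            seen.add(ti)
            if ti not in match_t or augment(match_t[ti], seen):
                match_t[ti] = di
                return True
        return False

    for di in range(len(dets)):
        augment(di, set())

    matched_d = set(match_t.values())
    tp = [(dets[di], true[ti]) for ti, di in sorted(match_t.items())]
    fp = [d for i, d in enumerate(dets) if i not in matched_d]
    fn = [t for i, t in enumerate(true) if i not in match_t]
    return Matching(tp=tp, fp=fp, fn=fn)


def prf1(matching: Matching | tuple[int, int, int]) -> PRF1:
    """Precision, sensitivity and F1 from a matching (or TP/FP/FN counts).

    Undefined ratios (no detections, or no truth) are reported as 0 with
    the corresponding ``*_defined`` flag cleared.
    """
    tp, fp, fn = matching.counts if isinstance(matching, Matching) else matching
    p_def, s_def = tp + fp > 0, tp + fn > 0
    p = tp / (tp + fp) if p_def else 0.0
    s = tp / (tp + fn) if s_def else 0.0
    f1 = 2 * p * s / (p + s) if p + s > 0 else 0.0
    return PRF1(p, s, f1, tp, fp, fn, p_def, s_def)


def pooled_prf1(matchings) -> PRF1:
    """Micro-averaged metrics over an ensemble of per-matrix matchings."""
    tp = sum(m.counts[0] for m in matchings)
    fp = sum(m.counts[1] for m in matchings)
    fn = sum(m.counts[2] for m in matchings)
    return prf1((tp, fp, fn))


def parameter_sweep(dataset, kernel: Kernel, *,
                    taus=(0.25, 0.3, 0.35, 0.4, 0.45),
                    min_separations=(3, 5),
                    tolerance_bins: int = 2,
                    max_empty_fraction: float | None = None,
                    max_dist_bins: int | None = None) -> pd.DataFrame:
    """Grid sweep of the detector over a labelled dataset.

    ``dataset`` is a list of (ContactMatrix, SimTruth).  The correlation
    map of each matrix is computed once and re-thresholded for every
    (pearson threshold, min separation) combination, so the sweep costs one
    correlation pass per matrix.  Returns a table with pooled precision,
    sensitivity and F1 per combination; the best-F1 row (ties broken by the
    smallest parameter pair) is flagged in the ``best`` column.
    """
    kern = kernel.standardised()
    if max_empty_fraction is None:
        max_empty_fraction = kern.defaults.max_empty_fraction
    combos = list(product(taus, min_separations))
    counts = {c: [0, 0, 0] for c in combos}

    for m, truth in dataset:
        mp = _prepare(m, max_dist_bins)
        chrom = mp.index.chrom_names[0]
        block = mp.block(chrom)
        vr = mp.block_valid(chrom)
        cmap = correlation_map(block, kern, valid_rows=vr,
                               max_dist_bins=max_dist_bins,
                               max_empty_fraction=max_empty_fraction)
        lo, _ = mp.index.extent(chrom)
        for tau in taus:
            foci = label_foci(cmap, tau)
            for ms in min_separations:
                dets = filter_detections(
                    foci, min_separation_bins=ms, kernel_shape=kern.shape,
                    valid_rows=vr, max_empty_fraction=max_empty_fraction)
                pairs = [(lo + d.bin1, lo + d.bin2) for d in dets]
                match = match_detections(pairs, truth.loops, tolerance_bins)
                tp, fp, fn = match.counts
                acc = counts[(tau, ms)]
                acc[0] += tp
                acc[1] += fp
                acc[2] += fn

    rows = []
    for (tau, ms) in combos:
        met = prf1(tuple(counts[(tau, ms)]))
        rows.append((tau, ms, met.precision, met.sensitivity, met.f1,
                     met.tp, met.fp, met.fn))
    df = pd.DataFrame(rows, columns=["pearson", "min_separation_bins",
                                     "precision", "sensitivity", "f1",
                                     "tp", "fp", "fn"])
    best = df.sort_values(["f1", "pearson", "min_separation_bins"],
                          ascending=[False, True, True], kind="mergesort").index[0]
    df["best"] = False
    df.loc[best, "best"] = True
    return df
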