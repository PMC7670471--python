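"""Turn correlation maps into discrete pattern calls.

Pipeline per scanned block: keep centres whose Pearson coefficient reaches
the detection threshold; group them into *foci* (connected components under
4-way adjacency, built as a sparse pixel-adjacency graph); discard foci of
fewer than two pixels; take each focus's argmax as the candidate coordinate;
then greedily accept candidates by decreasing score, discarding any
candidate too close (Chebyshev distance) to an already-accepted one or
whose window overlaps too many invalid pixels.

:func:`detect` composes the whole workflow (balance -> detrend -> correlate
-> label -> filter) over a genome-wide contact matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .correlate import CorrelationMap, correlation_map
from .io import ContactMatrix, Coordinate2D
from .kernels import Kernel
from .preprocess import balance_ice, detrend

__all__ = ["Focus", "Detection", "label_foci", "filter_detections", "detect"]


@dataclass
class Focus:
    """One connected component of above-threshold correlation pixels."""

    rows: np.ndarray
    cols: np.ndarray
    scores: np.ndarray

    @property
    def size(self) -> int:
        return int(self.rows.size)

    @property
    def argmax(self) -> tuple[int, int, float]:
        """(row, col, score) of the best pixel; ties -> smallest (row, col)."""
        best = np.max(self.scores)
        cand = np.flatnonzero(self.scores == best)
        order = np.lexsort((self.cols[cand], self.rows[cand]))
        k = cand[order[0]]
        return int(self.rows[k]), int(self.cols[k]), float(self.scores[k])


@dataclass
class Detection:
    """One called pattern: bin pair, genomic coordinates and score."""

    bin1: int
    bin2: int
    score: float
    focus_size: int
    coord: Coordinate2D | None = None


def label_foci(cmap: CorrelationMap, tau: float, min_size: int = 2) -> list[Focus]:
    """Connected components (4-connectivity) of the >= tau pixel set.

    The retained pixels form the nodes of a sparse adjacency graph (edges
    between horizontally or vertically adjacent pixels); its connected
    components are the correlation foci.  Foci with fewer than ``min_size``
    pixels are discarded.
    """
    keep = cmap.scores >= tau
    rows, cols, scores = cmap.rows[keep], cmap.cols[keep], cmap.scores[keep]
    d = rows.size
    if d == 0:
        return []
    key = rows.astype(np.int64) * (max(cmap.shape[1], 1) + 1) + cols
    lookup = {int(k): i for i, k in enumerate(key)}
    src, dst = [], []
    for di, dj in ((0, 1), (1, 0)):
        nb_key = (rows + di).astype(np.int64) * (max(cmap.shape[1], 1) + 1) + (cols + dj)
        for i, k in enumerate(nb_key):
            j = lookup.get(int(k))
            if j is not None:
                src.append(i)
                dst.append(j)
    adj = sp.coo_matrix((np.ones(len(src), dtype=bool), (src, dst)), shape=(d, d))
    n_comp, labels = connected_components(adj, directed=False)
    foci = []
    for c in range(n_comp):
        member = labels == c
        if member.sum() < min_size:
            continue
        foci.append(Focus(rows[member], cols[member], scores[member]))
    # deterministic order: by argmax position
    foci.sort(key=lambda f: f.argmax[:2])
    return foci


def filter_detections(foci: list[Focus], *,
                      min_separation_bins: int,
                      kernel_shape: tuple[int, int] | None = None,
                      valid_rows: np.ndarray | None = None,
                      valid_cols: np.ndarray | None = None,
                      max_empty_fraction: float = 0.3) -> list[Detection]:
    """Greedy selection of focus maxima.

    Candidates are scanned by decreasing score (ties broken by (row, col)).
    A candidate is accepted only if its Chebyshev distance to every
    already-accepted candidate is at least ``min_separation_bins`` and, when
    the valid-bin masks are given, if its kernel window overlaps at most
    ``max_empty_fraction`` invalid pixels.
    """
    cands = [(f.argmax, f.size) for f in foci]
    cands.sort(key=lambda t: (-t[0][2], t[0][0], t[0][1]))
    accepted: list[Detection] = []
    for (r, c, s), size in cands:
        if any(max(abs(r - a.bin1), abs(c - a.bin2)) < min_separation_bins
               for a in accepted):
            continue
        if kernel_shape is not None and valid_rows is not None:
            hm, hn = kernel_shape[0] // 2, kernel_shape[1] // 2
            vc = valid_rows if valid_cols is None else valid_cols
            win_r = valid_rows[max(0, r - hm): r + hm + 1]
            win_c = vc[max(0, c - hn): c + hn + 1]
            n_tot = kernel_shape[0] * kernel_shape[1]
            n_valid = int(win_r.sum()) * int(win_c.sum())
            if n_tot - n_valid > max_empty_fraction * n_tot:
                continue
        accepted.append(Detection(bin1=r, bin2=c, score=s, focus_size=size))
    accepted.sort(key=lambda a: (a.bin1, a.bin2))
    return accepted


def _prepare(m: ContactMatrix, max_dist_bins: int | None):
    """Balance and detrend a raw matrix; pass through an already-detrended one."""
    if m.is_detrended:
        return m
    if not m.is_balanced:
        m, _ = balance_ice(m)
    m, _ = detrend(m, max_dist_bins=None if max_dist_bins is None
                   else max_dist_bins + 32)
    return m


def detect(m: ContactMatrix, kernel: Kernel, *,
           pearson: float | None = None,
           min_dist_bp: int | None = None,
           max_dist_bp: int | None = None,
           min_separation_bins: int | None = None,
           max_empty_fraction: float | None = None,
           tsvd_rank: int | None = None,
           inter: bool | None = None,
           return_corr: bool = False):
    """End-to-end pattern detection on a genome-wide contact matrix.

    Raw matrices are balanced and detrended first; already-detrended input
    is scanned as-is.  Diagonal-pattern kernels scan the in-band upper
    triangle of every chromosome; trans-pattern kernels (or ``inter=True``)
    scan every inter-chromosomal block.  Returns detections in global bin
    coordinates, deterministically ordered; with ``return_corr`` also a dict
    of per-block correlation maps.
    """
    kern = kernel.standardised()
    defaults = kern.defaults
    tau = defaults.pearson_threshold if pearson is None else pearson
    if max_empty_fraction is None:
        max_empty_fraction = defaults.max_empty_fraction
    if min_separation_bins is None:
        min_separation_bins = (defaults.min_separation_bins
                               if defaults.min_separation_bins is not None
                               else kern.half_width)
    idx = m.index
    bs = idx.bin_size_bp

    def to_bins(bp, fallback):
        if bp is None:
            bp = fallback
        return None if bp is None else max(int(round(bp / bs)), 0)

    min_dist_bins = to_bins(min_dist_bp, defaults.min_dist_bp)
    max_dist_bins = to_bins(max_dist_bp, defaults.max_dist_bp)
    if inter is None:
        inter = kern.symmetry_mode == "trans-pattern"

    m = _prepare(m, max_dist_bins)
    detections: list[Detection] = []
    corr_maps: dict[tuple[str, str], CorrelationMap] = {}

    blocks: list[tuple[str, str]] = []
    if not inter:
        blocks = [(c, c) for c in idx.chrom_names]
    else:
        names = idx.chrom_names
        blocks = [(names[a], names[b]) for a in range(len(names))
                  for b in range(a + 1, len(names))]

    for c1, c2 in blocks:
        lo1, _ = idx.extent(c1)
        lo2, _ = idx.extent(c2)
        vr = m.block_valid(c1)
        vc = m.block_valid(c2)
        block = m.block(c1, c2)
        if min(block.shape) < max(kern.shape):
            continue
        cmap = correlation_map(
            block, kern,
            valid_rows=vr, valid_cols=vc if c1 != c2 else None,
            min_dist_bins=min_dist_bins, max_dist_bins=max_dist_bins,
            intra=(c1 == c2), max_empty_fraction=max_empty_fraction,
            tsvd_rank=tsvd_rank,
        )
        if return_corr:
            corr_maps[(c1, c2)] = cmap
        foci = label_foci(cmap, tau)
        dets = filter_detections(
            foci, min_separation_bins=min_separation_bins,
            kernel_shape=kern.shape, valid_rows=vr,
            valid_cols=vc if c1 != c2 else None,
            max_empty_fraction=max_empty_fraction,
        )
        for d in dets:
            b1, b2 = lo1 + d.bin1, lo2 + d.bin2
            if b1 > b2:
                b1, b2 = b2, b1
            detections.append(Detection(
                bin1=int(b1), bin2=int(b2), score=d.score,
                focus_size=d.focus_size,
                coord=Coordinate2D.from_bins(idx, int(b1), int(b2), d.score),
            ))

    detections.sort(key=lambda d: (d.bin1, d.bin2))
    return (detections, corr_maps) if return_corr else detections
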