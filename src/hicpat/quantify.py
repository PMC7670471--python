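"""Score fixed coordinates with a kernel, build pileups and loop spectra.

Quantification answers "how loop-like (border-like, ...) is the map at
these positions?" without de-novo detection: each supplied coordinate pair
is scored with exactly the same masked Pearson coefficient the detector
uses, so quantifying the detector's own output reproduces its scores
bit-for-bit.  Pileups average observed/expected windows over coordinate
sets; the loop spectrum aggregates quantified anchor-pair scores by genomic
separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlate import _score_tile
from .detect import _prepare
from .io import ContactMatrix, Coordinate2D
from .kernels import Kernel

__all__ = ["QuantifyResult", "quantify", "pileup", "loop_spectrum",
           "smooth_spectrum"]


@dataclass
class QuantifyResult:
    coord: Coordinate2D
    bin1: int
    bin2: int
    score: float          # NaN when unscorable
    status: str           # "ok" | "edge" | "masked" | "undefined" | "out-of-range"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _window(m: ContactMatrix, b1: int, b2: int, hm: int, hn: int):
    """Dense symmetric window around a global bin pair, or None at the edge.

    Returns (window values, validity mask).  Windows are cut from the
    chromosome-pair block with symmetric semantics, mirroring what the
    correlation scan sees.
    """
    idx = m.index
    c1, l1 = idx.to_local(b1)
    c2, l2 = idx.to_local(b2)
    c1, c2, l1, l2 = int(c1), int(c2), int(l1), int(l2)
    name1, name2 = idx.chrom_names[c1], idx.chrom_names[c2]
    block = m.block(name1, name2)
    vr = m.block_valid(name1)
    vc = vr if c1 == c2 else m.block_valid(name2)
    if not (hm <= l1 < block.shape[0] - hm and hn <= l2 < block.shape[1] - hn):
        return None
    win = block[l1 - hm:l1 + hm + 1, l2 - hn:l2 + hn + 1].toarray()
    vmask = np.outer(vr[l1 - hm:l1 + hm + 1], vc[l2 - hn:l2 + hn + 1])
    centre_valid = vr[l1] and vc[l2]
    return win, vmask, centre_valid


def quantify(m: ContactMatrix, coords, kernel: Kernel, *,
             max_empty_fraction: float | None = None) -> list[QuantifyResult]:
    """Masked Pearson score of the kernel at each supplied coordinate.

    ``coords`` may hold :class:`Coordinate2D` rows or (bin1, bin2) global
    bin pairs.  Raw matrices are balanced/detrended first.  Coordinates that
    cannot be scored (window over the matrix edge, too many masked pixels,
    constant window) are flagged via ``status`` and carry a NaN score.
    """
    kern = kernel.standardised()
    if max_empty_fraction is None:
        max_empty_fraction = kern.defaults.max_empty_fraction
    hm, hn = kern.shape[0] // 2, kern.shape[1] // 2
    min_valid = int(np.ceil((1.0 - max_empty_fraction) * kern.matrix.size))
    m = _prepare(m, None)
    out: list[QuantifyResult] = []
    for c in coords:
        if isinstance(c, Coordinate2D):
            try:
                b1, b2 = c.bins(m.index)
            except (KeyError, IndexError):
                out.append(QuantifyResult(c, -1, -1, np.nan, "out-of-range"))
                continue
            coord = c
        else:
            b1, b2 = int(c[0]), int(c[1])
            if b1 > b2:
                b1, b2 = b2, b1
            if not (0 <= b1 < m.n_bins and 0 <= b2 < m.n_bins):
                out.append(QuantifyResult(None, b1, b2, np.nan, "out-of-range"))
                continue
            coord = Coordinate2D.from_bins(m.index, b1, b2)
        got = _window(m, b1, b2, hm, hn)
        if got is None:
            out.append(QuantifyResult(coord, b1, b2, np.nan, "edge"))
            continue
        win, vmask, centre_valid = got
        if not centre_valid or vmask.sum() < max(min_valid, 2):
            out.append(QuantifyResult(coord, b1, b2, np.nan, "masked"))
            continue
        centre_ok = np.zeros_like(vmask)
        centre_ok[hm, hn] = True
        corr, defined = _score_tile(win, vmask, kern.matrix, centre_ok, min_valid)
        if not defined[hm, hn]:
            out.append(QuantifyResult(coord, b1, b2, np.nan, "undefined"))
            continue
        score = float(corr[hm, hn])
        out.append(QuantifyResult(
            Coordinate2D(coord.chrom1, coord.start1, coord.end1,
                         coord.chrom2, coord.start2, coord.end2, score),
            b1, b2, score, "ok"))
    return out


def pileup(m: ContactMatrix, coords, window_radius_bins: int = 8
           ) -> tuple[np.ndarray, int]:
    """Element-wise mean observed/expected window over a coordinate set.

    Windows overlapping the matrix edge are skipped; masked pixels are
    excluded per cell from the mean.  Radius 8 gives the conventional
    17 x 17 aggregate.  Returns (mean window, number of windows used).
    """
    r = int(window_radius_bins)
    m = _prepare(m, None)
    side = 2 * r + 1
    wins = []
    for c in coords:
        if isinstance(c, Coordinate2D):
            b1, b2 = c.bins(m.index)
        else:
            b1, b2 = int(c[0]), int(c[1])
        got = _window(m, b1, b2, r, r)
        if got is None:
            continue
        win, vmask, _ = got
        wins.append(np.where(vmask, win, np.nan))
    if not wins:
        raise ValueError("no usable window (all coordinates at edges?)")
    arr = np.stack(wins)
    cnt = np.isfinite(arr).sum(axis=0)
    mean = np.full((side, side), np.nan)
    for i in range(side):
        for j in range(side):
            if cnt[i, j] > 0:
                # exact summation keeps the mean independent of input order
                mean[i, j] = math.fsum(
                    v for v in arr[:, i, j] if np.isfinite(v)) / cnt[i, j]
    return mean, len(wins)


def loop_spectrum(m: ContactMatrix, anchors, kernel: Kernel, *,
                  max_dist_bp: int = 1_000_000,
                  bucket_width_bins: int = 2,
                  n_boot: int = 1000,
                  seed: int = 0) -> pd.DataFrame:
    """Mean kernel score of anchor pairs as a function of their separation.

    ``anchors`` is a list of (chrom, position_bp).  All intra-chromosomal
    anchor pairs separated by at most ``max_dist_bp`` are scored with
    :func:`quantify`; scores are bucketed by pair distance (bucket width in
    bins) and summarised by the bucket mean with a seeded nonparametric
    bootstrap 95% CI.  Buckets with a single score carry NaN CIs (flagged by
    ``ci_defined``); empty buckets are absent from the table.
    """
    idx = m.index
    bs = idx.bin_size_bp
    max_d = max(int(round(max_dist_bp / bs)), 1)
    m = _prepare(m, None)

    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in anchors:
        by_chrom.setdefault(str(chrom), []).append(idx.bin_of(str(chrom), int(pos)))
    pairs: list[tuple[int, int]] = []
    for chrom, bins in by_chrom.items():
        bins = sorted(set(bins))
        for a in range(len(bins)):
            for b in range(a + 1, len(bins)):
                if bins[b] - bins[a] <= max_d:
                    pairs.append((bins[a], bins[b]))
    results = quantify(m, pairs, kernel)
    dist = np.array([r.bin2 - r.bin1 for r in results if r.ok])
    score = np.array([r.score for r in results if r.ok])
    if dist.size == 0:
        return pd.DataFrame(columns=["distance_bp", "n", "mean_score",
                                     "ci_lo", "ci_hi", "ci_defined"])
    rng = np.random.default_rng(seed)
    rows = []
    for bucket in np.unique(dist // bucket_width_bins):
        sel = (dist // bucket_width_bins) == bucket
        vals = score[sel]
        centre_bins = bucket * bucket_width_bins + bucket_width_bins / 2.0
        mean = float(vals.mean())
        if vals.size > 1:
            boots = rng.choice(vals, size=(n_boot, vals.size), replace=True).mean(axis=1)
            lo, hi = np.percentile(boots, [2.5, 97.5])
            ci = (float(lo), float(hi), True)
        else:
            ci = (np.nan, np.nan, False)
        rows.append((centre_bins * bs, int(vals.size), mean, *ci))
    return pd.DataFrame(rows, columns=["distance_bp", "n", "mean_score",
                                       "ci_lo", "ci_hi", "ci_defined"])


def smooth_spectrum(spectrum: pd.DataFrame, frac: float = 0.3) -> pd.DataFrame:
    """Lowess-smoothed copy of a spectrum for plotting (table left intact)."""
    from statsmodels.nonparametric.smoothers_lowess import lowess
    out = spectrum.copy()
    if len(out) >= 3:
        sm = lowess(out["mean_score"], out["distance_bp"], frac=frac,
                    return_sorted=False)
        out["smoothed_score"] = sm
    else:
        out["smoothed_score"] = out["mean_score"]
    return out
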