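"""Masked Pearson correlation of a kernel over a contact-map block.

For every candidate centre the kernel is compared with the window of the
observed/expected map around that centre, using the Pearson coefficient
computed only over *valid* pixels — positions whose bin row and column are
not masked.  Structural zeros at valid bins are data (a detrended zero);
only masked-bin pixels are excluded.  Windows truncated by the matrix edge
are not scored (zero-padding would bias the window mean), and centres whose
window overlaps too many invalid pixels, or whose window is constant, are
masked rather than set to 0.

The implementation expresses the per-window means, variances and the
cross-term as a handful of box/kernel cross-correlations of the masked
image, so the result is exactly the textbook masked Pearson coefficient at
every scored centre (the unit tests compare against a brute-force oracle).
A truncated-SVD path replaces the kernel-shaped correlations by separable
rank-1 passes to cut work for large kernels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import correlate as _correlate
from scipy.ndimage import correlate1d as _correlate1d

from .kernels import Kernel, tsvd_approximate, reconstruct_tsvd

__all__ = ["CorrelationMap", "correlation_map", "correlation_map_tsvd"]

# a window is "constant" when its variance is this small relative to its energy
_VAR_RTOL = 1e-12


@dataclass
class CorrelationMap:
    """Sparse map of Pearson coefficients over one contact-matrix block.

    ``rows``/``cols``/``scores`` list the scored centres (block-local
    indices); everything not listed was either outside the scan band or
    masked (edge overlap, too many invalid pixels, or undefined
    coefficient).  ``shape`` is the block shape.
    """

    shape: tuple[int, int]
    rows: np.ndarray
    cols: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.scores.size and (np.nanmax(np.abs(self.scores)) > 1 + 1e-9):
            raise ValueError("Pearson coefficients must lie in [-1, 1]")

    @property
    def n_scored(self) -> int:
        return int(self.rows.size)

    def dense(self, fill: float = np.nan) -> np.ndarray:
        out = np.full(self.shape, fill)
        out[self.rows, self.cols] = self.scores
        return out

    def to_coo(self) -> sp.coo_matrix:
        return sp.coo_matrix((self.scores, (self.rows, self.cols)), shape=self.shape)


def _kernel_sums(valid: np.ndarray, img_v: np.ndarray, kmat: np.ndarray,
                 factors=None):
    """Correlations of mask and masked image with the kernel (and its square).

    Returns (S_K, S_K2, S_IK): per-centre sums over valid window pixels of
    K, K^2 and I*K.  With ``factors`` (tSVD) the K-shaped correlations are
    evaluated as separable rank-1 passes of the reconstructed kernel.
    """
    if factors is None:
        s_k = _correlate(valid, kmat, mode="constant", cval=0.0)
        s_k2 = _correlate(valid, kmat * kmat, mode="constant", cval=0.0)
        s_ik = _correlate(img_v, kmat, mode="constant", cval=0.0)
        return s_k, s_k2, s_ik
    krec = reconstruct_tsvd(factors)
    s_k = np.zeros_like(valid)
    s_ik = np.zeros_like(valid)
    for sigma, u, v in factors:
        for target, arr in ((s_k, valid), (s_ik, img_v)):
            t = _correlate1d(arr, sigma * u, axis=0, mode="constant", cval=0.0)
            t = _correlate1d(t, v, axis=1, mode="constant", cval=0.0)
            target += t
    s_k2 = _correlate(valid, krec * krec, mode="constant", cval=0.0)
    return s_k, s_k2, s_ik


def _score_tile(img: np.ndarray, valid: np.ndarray, kmat: np.ndarray,
                centre_ok: np.ndarray, min_valid: int, factors=None):
    """Masked Pearson coefficients for every centre flagged in ``centre_ok``."""
    ones = np.ones_like(kmat)
    v = valid.astype(float)
    img_v = np.where(valid, img, 0.0)
    w = _correlate(v, ones, mode="constant", cval=0.0)
    s_i = _correlate(img_v, ones, mode="constant", cval=0.0)
    s_i2 = _correlate(img_v * img_v, ones, mode="constant", cval=0.0)
    s_k, s_k2, s_ik = _kernel_sums(v, img_v, kmat, factors)

    ok = centre_ok & (np.rint(w).astype(int) >= max(min_valid, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        var_i = s_i2 - s_i * s_i / w
        var_k = s_k2 - s_k * s_k / w
        cov = s_ik - s_i * s_k / w
    defined = ok & (var_i > _VAR_RTOL * np.maximum(s_i2, 1e-300)) \
        & (var_k > _VAR_RTOL * np.maximum(s_k2, 1e-300))
    corr = np.zeros_like(img)
    np.divide(cov, np.sqrt(var_i * var_k), out=corr, where=defined)
    np.clip(corr, -1.0, 1.0, out=corr)
    return corr, defined


def correlation_map(block, kernel: Kernel, *,
                    valid_rows: np.ndarray | None = None,
                    valid_cols: np.ndarray | None = None,
                    min_dist_bins: int | None = None,
                    max_dist_bins: int | None = None,
                    intra: bool = True,
                    max_empty_fraction: float | None = None,
                    tsvd_rank: int | None = None,
                    tile_rows: int = 2048) -> CorrelationMap:
    """Correlate a kernel over a (sub-)matrix block.

    Parameters
    ----------
    block
        Dense array or scipy sparse matrix of observed/expected values.  For
        an intra-chromosomal block pass the full symmetric square.
    valid_rows, valid_cols
        Boolean masks of usable bins along each axis (for an intra block
        they coincide).  Pixels on invalid rows/columns are excluded from
        every window's valid set; invalid centres are never scored.
    min_dist_bins, max_dist_bins
        With ``intra=True``, restrict centres to the upper-triangle band
        ``min_dist <= col - row <= max_dist``.  ``min_dist_bins=None``
        defaults to kernel half-width + 1 (windows never straddle the
        diagonal mirror); ``max_dist_bins=None`` scans the whole triangle.
    intra
        False for an inter-chromosomal block: every centre is scanned and no
        band applies.
    max_empty_fraction
        Centres whose window has more than this fraction of invalid pixels
        are masked (default from the kernel).
    tsvd_rank
        If given, run the truncated-SVD separable path at this rank.
    tile_rows
        Row-chunk size for banded scans; bounds memory on large maps without
        changing results.
    """
    kern = kernel.standardised()
    kmat = kern.matrix
    hm, hn = kmat.shape[0] // 2, kmat.shape[1] // 2
    if sp.issparse(block):
        n_rows, n_cols = block.shape
    else:
        block = np.asarray(block, dtype=float)
        n_rows, n_cols = block.shape
    if kmat.shape[0] > n_rows or kmat.shape[1] > n_cols:
        raise ValueError("kernel larger than the scanned block")
    if valid_rows is None:
        valid_rows = np.ones(n_rows, dtype=bool)
    if valid_cols is None:
        valid_cols = np.ones(n_cols, dtype=bool) if not intra else valid_rows
    if max_empty_fraction is None:
        max_empty_fraction = kern.defaults.max_empty_fraction
    min_valid = int(np.ceil((1.0 - max_empty_fraction) * kmat.size))
    # factor the kernel as supplied: Pearson is affine-invariant, and the
    # raw template may be exactly low-rank where its standardised form is not
    factors = tsvd_approximate(kernel, tsvd_rank) if tsvd_rank is not None else None

    if intra:
        if n_rows != n_cols:
            raise ValueError("intra block must be square")
        lo_d = hm + 1 if min_dist_bins is None else max(min_dist_bins, 0)
        hi_d = n_cols - 1 if max_dist_bins is None else min(max_dist_bins, n_cols - 1)
    else:
        lo_d, hi_d = None, None

    rows_out, cols_out, vals_out = [], [], []
    margin_c = (hi_d + hn) if intra else 0
    step = max(tile_rows, 4 * max(hm, hn) + 8)
    for r0 in range(0, n_rows, step):
        r1 = min(n_rows, r0 + step)
        rr0, rr1 = max(0, r0 - hm), min(n_rows, r1 + hm)
        if intra:
            cc0 = max(0, r0 + lo_d - hn)
            cc1 = min(n_cols, r1 + margin_c)
            if cc0 >= cc1:
                continue
        else:
            cc0, cc1 = 0, n_cols
        sub = block[rr0:rr1, cc0:cc1]
        sub = sub.toarray() if sp.issparse(sub) else np.asarray(sub, dtype=float)
        vmask = np.outer(valid_rows[rr0:rr1], valid_cols[cc0:cc1])

        i_loc = np.arange(rr0, rr1)
        j_loc = np.arange(cc0, cc1)
        # full window inside the *global* block, centre on valid bins
        row_ok = (i_loc >= hm) & (i_loc < n_rows - hm) & valid_rows[rr0:rr1] \
            & (i_loc >= r0) & (i_loc < r1)
        col_ok = (j_loc >= hn) & (j_loc < n_cols - hn) & valid_cols[cc0:cc1]
        centre_ok = np.outer(row_ok, col_ok)
        if intra:
            dist = j_loc[None, :] - i_loc[:, None]
            centre_ok &= (dist >= lo_d) & (dist <= hi_d)
        if not centre_ok.any():
            continue

        corr, defined = _score_tile(sub, vmask, kmat, centre_ok, min_valid, factors)
        ii, jj = np.nonzero(defined)
        rows_out.append(ii + rr0)
        cols_out.append(jj + cc0)
        vals_out.append(corr[ii, jj])

    if rows_out:
        rows = np.concatenate(rows_out)
        cols = np.concatenate(cols_out)
        vals = np.concatenate(vals_out)
        order = np.lexsort((cols, rows))
        rows, cols, vals = rows[order], cols[order], vals[order]
    else:
        rows = np.empty(0, dtype=int)
        cols = np.empty(0, dtype=int)
        vals = np.empty(0, dtype=float)
    return CorrelationMap(shape=(n_rows, n_cols), rows=rows, cols=cols, scores=vals)


def correlation_map_tsvd(block, kernel: Kernel, rank: int, **kw) -> CorrelationMap:
    """Truncated-SVD accelerated variant of :func:`correlation_map`.

    At full rank the reconstruction is exact and the output matches the
    exact path to float tolerance; at lower ranks the kernel is approximated
    by its leading singular vectors.
    """
    return correlation_map(block, kernel, tsvd_rank=rank, **kw)
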