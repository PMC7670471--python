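"""Normalisation, detrending and masking of contact maps.

Three steps prepare a raw map for template matching:

1. ICE balancing — iterative correction that equalises the marginal sum of
   every valid bin, removing coverage biases.
2. Missing-bin detection — bins with anomalously low coverage ("white
   lines") are flagged invalid and ignored everywhere downstream.
3. Detrending — each intra-chromosomal pixel is divided by the mean of its
   diagonal (the empirical distance-decay P(s)), turning contacts into
   observed/expected ratios; contacts beyond a maximum scan distance are
   dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import ContactMatrix

__all__ = [
    "ExpectedProfile",
    "balance_ice",
    "detect_missing_bins",
    "detrend",
]


@dataclass
class ExpectedProfile:
    """Per-diagonal mean contact value P(s), per chromosome.

    ``expected[chrom][s]`` is the mean over valid-bin positions of diagonal
    ``s`` (in bins).  Diagonals with no valid position hold NaN.
    """

    expected: dict[str, np.ndarray]
    bin_size_bp: int

    def to_frame(self):
        import pandas as pd
        rows = []
        for chrom, vals in self.expected.items():
            rows.append(pd.DataFrame({
                "chrom": chrom,
                "distance_bp": np.arange(len(vals)) * self.bin_size_bp,
                "expected": vals,
            }))
        return pd.concat(rows, ignore_index=True)


def detect_missing_bins(m: ContactMatrix, n_mads: float = 3.0,
                        min_nonzero: int = 1) -> np.ndarray:
    """Flag low-coverage bins as invalid.

    A bin is invalid when its number of nonzero pixels falls below
    ``median - n_mads * MAD`` of the per-bin nonzero counts (computed over
    bins with any signal), or below ``min_nonzero``.  Zero-contact bins are
    always invalid.  Returns the boolean valid mask (does not mutate ``m``).
    """
    mat = m.matrix
    binary = mat.copy()
    binary.data = np.ones_like(binary.data)
    # symmetric nonzero count per bin; diagonal counted once
    nnz = np.asarray(binary.sum(axis=0)).ravel() + np.asarray(binary.sum(axis=1)).ravel()
    diag = mat.diagonal()
    nnz = nnz - (diag != 0)
    covered = nnz[nnz > 0]
    floor = float(min_nonzero)
    if covered.size:
        med = np.median(covered)
        mad = np.median(np.abs(covered - med))
        floor = max(floor, med - n_mads * 1.4826 * mad)
    return nnz >= floor


def balance_ice(m: ContactMatrix, max_iter: int = 300, tol: float = 1e-5,
                n_mads: float = 3.0) -> tuple[ContactMatrix, np.ndarray]:
    """Whole-genome ICE (iterative correction) balancing.

    Rescales the matrix as ``M'[i,j] = M[i,j] / (b[i] * b[j])`` with biases
    iterated until every valid bin's marginal sum is equal (coefficient of
    variation of the marginals below ``tol``).  Low-coverage bins detected by
    :func:`detect_missing_bins` are flagged invalid, excluded from the
    iteration, and their bias set to NaN.

    Returns the balanced matrix (marginals normalised to mean 1 over valid
    bins) and the bias vector.
    """
    if m.matrix.nnz == 0 or m.matrix.sum() == 0:
        raise ValueError("cannot balance an all-zero matrix")
    valid = m.valid_bins & detect_missing_bins(m, n_mads=n_mads)
    n = m.n_bins
    coo = sp.triu(m.matrix).tocoo()
    keep = valid[coo.row] & valid[coo.col]
    row, col, data = coo.row[keep], coo.col[keep], coo.data[keep].astype(float)

    bias = np.ones(n)
    converged = False
    for _ in range(max_iter):
        w = data / (bias[row] * bias[col])
        marg = np.bincount(row, weights=w, minlength=n) + \
            np.bincount(col, weights=w, minlength=n)
        marg -= np.bincount(row[row == col],
                            weights=w[row == col], minlength=n)
        mvalid = marg[valid]
        mean = mvalid.mean()
        if mean == 0:
            raise ValueError("valid bins have zero coverage")
        cv = mvalid.std() / mean
        if cv < tol:
            converged = True
            break
        update = np.where(valid & (marg > 0), marg / mean, 1.0)
        bias *= update
    if not converged:
        warnings.warn(f"ICE did not reach tol={tol} within {max_iter} iterations "
                      f"(marginal CV {cv:.2e}); returning last iterate")

    # normalise so valid-bin marginals average 1
    w = data / (bias[row] * bias[col])
    marg = np.bincount(row, weights=w, minlength=n) + \
        np.bincount(col, weights=w, minlength=n)
    marg -= np.bincount(row[row == col], weights=w[row == col], minlength=n)
    scale = marg[valid].mean()
    w = w / scale
    bias = bias * np.sqrt(scale)
    bias[~valid] = np.nan

    out = sp.coo_matrix((w, (row, col)), shape=(n, n)).tocsr()
    balanced = m.copy_with(matrix=out, valid_bins=valid,
                           is_balanced=True, bias=bias)
    return balanced, bias


def detrend(m: ContactMatrix, max_dist_bins: int | None = None
            ) -> tuple[ContactMatrix, ExpectedProfile]:
    """Convert a balanced map to observed/expected ratios per chromosome.

    Each intra-chromosomal pixel at bin distance ``s`` is divided by the mean
    value of diagonal ``s`` over that chromosome's valid-bin positions
    (structural zeros at valid positions count toward the mean).  Diagonals
    whose mean is zero or undefined are left untouched.  Intra-chromosomal
    pixels beyond ``max_dist_bins`` are discarded; inter-chromosomal pixels
    are divided by the mean of their trans block over valid bins.
    """
    if not m.is_balanced:
        warnings.warn("detrending a matrix that was not balanced")
    idx = m.index
    masked = m.mask_invalid()
    coo = sp.triu(masked.matrix).tocoo()
    row, col, data = coo.row, coo.col, coo.data.astype(float)
    off = idx.chrom_bin_offsets
    cid_row = np.searchsorted(off, row, side="right") - 1
    cid_col = np.searchsorted(off, col, side="right") - 1

    new_data = data.copy()
    keep = np.ones(len(data), dtype=bool)
    expected: dict[str, np.ndarray] = {}

    for cid, chrom in enumerate(idx.chrom_names):
        lo, hi = int(off[cid]), int(off[cid + 1])
        nb = hi - lo
        valid = m.valid_bins[lo:hi]
        in_chrom = (cid_row == cid) & (cid_col == cid)
        s = col[in_chrom] - row[in_chrom]
        max_s = nb - 1 if max_dist_bins is None else min(max_dist_bins, nb - 1)
        # valid position count on each diagonal
        counts = np.array([
            np.count_nonzero(valid[: nb - d] & valid[d:]) for d in range(max_s + 1)
        ], dtype=float)
        sums = np.bincount(s[s <= max_s], weights=new_data[in_chrom][s <= max_s],
                           minlength=max_s + 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(counts > 0, sums / counts, np.nan)
        expected[chrom] = means
        sel = np.flatnonzero(in_chrom)
        too_far = s > max_s
        keep[sel[too_far]] = False
        ok = ~too_far
        mean_at = means[s[ok]]
        divisible = np.isfinite(mean_at) & (mean_at > 0)
        tgt = sel[ok][divisible]
        new_data[tgt] = new_data[tgt] / mean_at[divisible]

    # trans blocks: observed / block mean over valid-bin positions
    trans = cid_row != cid_col
    if np.any(trans):
        n_valid = np.array([m.valid_bins[int(off[c]):int(off[c + 1])].sum()
                            for c in range(idx.n_chroms)], dtype=float)
        pair_key = cid_row * idx.n_chroms + cid_col
        for key in np.unique(pair_key[trans]):
            c1, c2 = divmod(int(key), idx.n_chroms)
            if c1 == c2:
                continue
            sel = np.flatnonzero(pair_key == key)
            denom = n_valid[c1] * n_valid[c2]
            if denom > 0:
                mean = new_data[sel].sum() / denom
                if mean > 0:
                    new_data[sel] = new_data[sel] / mean

    out = sp.coo_matrix((new_data[keep], (row[keep], col[keep])),
                        shape=m.matrix.shape).tocsr()
    detrended = m.copy_with(matrix=out, is_detrended=True)
    return detrended, ExpectedProfile(expected, idx.bin_size_bp)
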