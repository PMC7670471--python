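"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by the most literal route
available (dense brute force, flood fill, optimal assignment) so the
optimised implementations are checked against independent computations.
"""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

import hicpat as hp


# ---------------------------------------------------------------------------
# oracles

def masked_pearson_oracle(img: np.ndarray, valid: np.ndarray,
                          kernel: np.ndarray, min_valid: int):
    """Brute-force masked Pearson at every full-window centre.

    Returns (scores, defined): per-centre coefficient computed with the
    textbook two-pass formula over the valid pixels of each window, and a
    mask of centres where the coefficient is defined (full window inside
    the image, valid centre, enough valid pixels, non-constant factors).
    """
    n_r, n_c = img.shape
    hm, hn = kernel.shape[0] // 2, kernel.shape[1] // 2
    scores = np.full((n_r, n_c), np.nan)
    defined = np.zeros((n_r, n_c), dtype=bool)
    for i in range(hm, n_r - hm):
        for j in range(hn, n_c - hn):
            if not (valid[i, j]):
                continue
            win = img[i - hm:i + hm + 1, j - hn:j + hn + 1]
            sel = valid[i - hm:i + hm + 1, j - hn:j + hn + 1]
            if sel.sum() < max(min_valid, 2):
                continue
            x = win[sel].astype(float)
            y = kernel[sel].astype(float)
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            scores[i, j] = r
            defined[i, j] = True
    return scores, defined


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """4-connectivity connected components of a boolean grid by flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if not mask[i, j] or seen[i, j]:
                continue
            stack = [(i, j)]
            comp = set()
            seen[i, j] = True
            while stack:
                r, c = stack.pop()
                comp.add((r, c))
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1] \
                            and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            comps.append(comp)
    return comps


def optimal_tp_count(dets, truth, tol: int) -> int:
    """Maximum-cardinality one-to-one matching within tolerance (assignment)."""
    from scipy.optimize import linear_sum_assignment
    if not dets or not truth:
        return 0
    big = 10 ** 6
    cost = np.full((len(dets), len(truth)), big, dtype=float)
    for i, (r, c) in enumerate(dets):
        for j, (tr, tc) in enumerate(truth):
            d = max(abs(r - tr), abs(c - tc))
            if d <= tol:
                cost[i, j] = d
    ri, ci = linear_sum_assignment(cost)
    return int(np.sum(cost[ri, ci] < big))


# ---------------------------------------------------------------------------
# fixture builders

def toy_matrix(dense: np.ndarray, bin_size: int = 2000,
               chroms: tuple[tuple[str, int], ...] | None = None,
               **flags) -> hp.ContactMatrix:
    """ContactMatrix from a dense symmetric (or upper) array, one chromosome
    unless ``chroms`` gives (name, n_bins) blocks."""
    n = dense.shape[0]
    if chroms is None:
        idx = hp.GenomeIndex(("chr1",), (n * bin_size,), bin_size)
    else:
        assert sum(nb for _, nb in chroms) == n
        idx = hp.GenomeIndex(tuple(c for c, _ in chroms),
                             tuple(nb * bin_size for _, nb in chroms), bin_size)
    upper = np.triu(dense)
    return hp.ContactMatrix(idx, sp.csr_matrix(upper), **flags)


def planted_kernel_matrix(kernel: hp.Kernel, n: int = 120, at=(40, 90),
                          scale: float = 2.0, offset: float = 5.0
                          ) -> hp.ContactMatrix:
    """Noiseless detrended-style matrix holding one affine kernel copy."""
    k = kernel.standardised()
    h = k.shape[0] // 2
    dense = np.zeros((n, n))
    r, c = at
    dense[r - h:r + h + 1, c - h:c + h + 1] = scale * k.matrix + offset
    return toy_matrix(dense, is_balanced=True, is_detrended=True)


@pytest.fixture(scope="session")
def loops_kernel() -> hp.Kernel:
    return hp.builtin_kernel("loops")


@pytest.fixture(scope="session")
def small_dataset():
    """Five labelled synthetic matrices under the default study conditions."""
    cfg = hp.SimConfig(seed=11)
    data, _ = hp.simulate_dataset(cfg, n_matrices=5)
    return data


@pytest.fixture(scope="session")
def sim_matrix(small_dataset):
    return small_dataset[0]
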