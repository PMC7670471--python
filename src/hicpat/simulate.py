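"""Labelled synthetic Hi-C matrices for testing and benchmarking.

The generator follows a bootstrap recipe: a probability map for one
chromosome is assembled as the product of three factor maps —

1. a diagonal gradient from the distance-decay curve P(s) (the polymer
   background),
2. a border map placing domain-boundary templates on the diagonal at
   normally-distributed spacings,
3. a loop map placing loop templates 2-100 pixels off the diagonal, each
   aligned vertically and horizontally with border positions —

then normalised to a probability law over the upper triangle and sampled
with a multinomial draw of a fixed read budget.  The planted loop and
border coordinates are returned as ground truth, so detection quality can
be scored without any external data.

Real maps are bootstrapped from empirical P(s) curves and pattern pileups;
this module ships parametric stand-ins (power-law P(s), analytic smooth
templates) and accepts user-supplied tables/templates to emulate a specific
experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import scipy.sparse as sp

from .io import ContactMatrix, GenomeIndex

__all__ = [
    "SimConfig",
    "SimTruth",
    "default_ps",
    "loop_template",
    "border_template",
    "hairpin_template",
    "build_probability_map",
    "sample_matrix",
    "simulate_dataset",
    "simulate_trans_map",
]


def default_ps(n: int, slope: float = -1.5, floor: float = 1e-3) -> np.ndarray:
    """Power-law contact-decay curve P(s) ~ s^slope over n bin distances."""
    s = np.arange(n, dtype=float)
    p = np.maximum(s, 1.0) ** slope
    p[0] = 1.5  # the self-contact diagonal is the strongest
    return np.maximum(p, floor)


def loop_template(size: int = 17, intensity: float = 3.0,
                  sigma: float = 1.8) -> np.ndarray:
    """Multiplicative loop factor: a focal Gaussian dot (background 1)."""
    h = size // 2
    m, n = np.mgrid[-h:h + 1, -h:h + 1]
    return 1.0 + intensity * np.exp(-(m ** 2 + n ** 2) / (2.0 * sigma ** 2))


def border_template(size: int = 17, strength: float = 0.8,
                    reach: float = 5.0) -> np.ndarray:
    """Multiplicative border factor: same-side quadrants enriched, contacts
    crossing the boundary depleted (an insulation corner on the diagonal)."""
    h = size // 2
    m, n = np.mgrid[-h:h + 1, -h:h + 1]
    side = np.where(m * n > 0, 1.0, np.where(m * n < 0, -1.0, 0.0))
    weight = np.exp(-(m ** 2 + n ** 2) / (2.0 * reach ** 2))
    return np.exp(strength * side * weight)


def hairpin_template(size: int = 17, intensity: float = 2.5,
                     width: float = 1.5, reach: float = 6.0) -> np.ndarray:
    """Multiplicative hairpin factor: a short stripe perpendicular to the
    main diagonal (enrichment along the anti-diagonal of the window)."""
    h = size // 2
    m, n = np.mgrid[-h:h + 1, -h:h + 1]
    return 1.0 + intensity * np.exp(-((m + n) ** 2) / (2.0 * width ** 2)) \
        * np.exp(-(m ** 2 + n ** 2) / (2.0 * reach ** 2))


@dataclass
class SimConfig:
    """Study conditions of the synthetic generator.

    Defaults emulate a mitotic yeast chromosome binned at 2 kb: a 289-bin
    map, domain borders every ~20 bins (SD 8), loops on border pairs 2-100
    bins apart, and 500k contacts per matrix.
    """

    matrix_size_bins: int = 289
    n_matrices: int = 2000
    read_budget: int = 500_000
    bin_size_bp: int = 2000
    chrom_name: str = "chrS"
    ps: np.ndarray | None = None          # table P(s); None -> power law
    ps_slope: float = -1.5
    border_spacing_mean: float = 20.0
    border_spacing_sd: float = 8.0
    border_spacing_min: int = 6
    border_tpl: np.ndarray | None = None  # None -> analytic 17x17
    loop_tpl: np.ndarray | None = None    # None -> analytic 17x17
    loop_intensity: float = 3.0
    loop_min_dist: int = 2
    loop_max_dist: int = 100
    loop_probability: float = 0.5
    seed: int = 0

    def resolved_ps(self) -> np.ndarray:
        if self.ps is not None:
            p = np.asarray(self.ps, dtype=float)
            if p.size < self.matrix_size_bins:
                raise ValueError("P(s) table shorter than the matrix")
            if not np.any(p > 0):
                raise ValueError("degenerate P(s): all zero")
            return p
        return default_ps(self.matrix_size_bins, self.ps_slope)

    def resolved_templates(self) -> tuple[np.ndarray, np.ndarray]:
        b = self.border_tpl if self.border_tpl is not None else border_template()
        l = self.loop_tpl if self.loop_tpl is not None \
            else loop_template(intensity=self.loop_intensity)
        for t in (b, l):
            t = np.asarray(t)
            if t.shape[0] % 2 == 0 or t.shape[0] != t.shape[1]:
                raise ValueError("templates must be odd square matrices")
            if t.shape[0] > self.matrix_size_bins:
                raise ValueError("template larger than the matrix")
        return np.asarray(b, float), np.asarray(l, float)

    def manifest(self) -> dict:
        d = asdict(self)
        for k in ("ps", "border_tpl", "loop_tpl"):
            if d[k] is not None:
                d[k] = np.asarray(d[k]).tolist()
        return d


@dataclass
class SimTruth:
    """Ground truth attached to one simulated matrix."""

    loops: list[tuple[int, int]]   # (bin1, bin2) with bin1 < bin2
    borders: list[int]             # diagonal bin positions

    def loop_array(self) -> np.ndarray:
        return np.array(self.loops, dtype=int).reshape(-1, 2)


def _stamp(factor_map: np.ndarray, tpl: np.ndarray, r: int, c: int) -> None:
    """Multiply a template into a factor map centred at (r, c), clipped."""
    h = tpl.shape[0] // 2
    n = factor_map.shape[0]
    r0, r1 = max(0, r - h), min(n, r + h + 1)
    c0, c1 = max(0, c - h), min(n, c + h + 1)
    factor_map[r0:r1, c0:c1] *= tpl[r0 - r + h:r1 - r + h, c0 - c + h:c1 - c + h]


def build_probability_map(cfg: SimConfig, seed: int | np.random.Generator | None = None
                          ) -> tuple[np.ndarray, SimTruth]:
    """Assemble the product probability map and its ground truth.

    Returns an upper-triangular (including diagonal) matrix normalised to
    sum 1, plus the planted loop/border coordinates.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.matrix_size_bins
    ps = cfg.resolved_ps()
    border_tpl, loop_tpl = cfg.resolved_templates()

    i, j = np.triu_indices(n)
    prob = np.zeros((n, n))
    prob[i, j] = ps[j - i]

    # borders: cumulative normal spacings along the diagonal
    borders: list[int] = []
    pos = float(rng.normal(cfg.border_spacing_mean, cfg.border_spacing_sd))
    while pos < n - 1:
        b = int(round(pos))
        if 0 < b < n:
            borders.append(b)
        step = rng.normal(cfg.border_spacing_mean, cfg.border_spacing_sd)
        pos += max(step, float(cfg.border_spacing_min))
    factor = np.ones((n, n))
    for b in borders:
        _stamp(factor, border_tpl, b, b)

    # loops: on border pairs within the distance range, aligned row+column
    loops: list[tuple[int, int]] = []
    for a in range(len(borders)):
        for b in range(a + 1, len(borders)):
            d = borders[b] - borders[a]
            if d < cfg.loop_min_dist or d > cfg.loop_max_dist:
                continue
            if rng.random() >= cfg.loop_probability:
                continue
            loops.append((borders[a], borders[b]))
            _stamp(factor, loop_tpl, borders[a], borders[b])

    prob *= np.triu(factor)
    total = prob.sum()
    if total <= 0:
        raise ValueError("degenerate probability map (all zero)")
    prob /= total
    return prob, SimTruth(loops=loops, borders=borders)


def _index_for(cfg: SimConfig) -> GenomeIndex:
    return GenomeIndex((cfg.chrom_name,),
                       (cfg.matrix_size_bins * cfg.bin_size_bp,),
                       cfg.bin_size_bp)


def sample_matrix(prob_map: np.ndarray, read_budget: int,
                  seed: int | np.random.Generator | None = None,
                  index: GenomeIndex | None = None) -> ContactMatrix:
    """Multinomial draw of ``read_budget`` contacts from a probability map.

    The total of the sampled counts equals the read budget exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = prob_map.shape[0]
    if index is None:
        index = GenomeIndex(("chrS",), (n * 2000,), 2000)
    i, j = np.triu_indices(n)
    p = prob_map[i, j].astype(float)
    total = p.sum()
    if not np.isclose(total, 1.0, rtol=1e-6):
        raise ValueError("prob_map must sum to 1 over the upper triangle")
    counts = rng.multinomial(int(read_budget), p / total)
    nz = counts > 0
    mat = sp.coo_matrix((counts[nz].astype(float), (i[nz], j[nz])),
                        shape=(index.n_bins, index.n_bins)).tocsr()
    return ContactMatrix(index=index, matrix=mat)


def simulate_dataset(cfg: SimConfig, n_matrices: int | None = None):
    """Generate ``n_matrices`` independent labelled matrices.

    Each draw gets its own child seed derived deterministically from the
    config's master seed.  Returns (list of (ContactMatrix, SimTruth),
    manifest dict recording all parameters).
    """
    n = cfg.n_matrices if n_matrices is None else n_matrices
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(n)
    idx = _index_for(cfg)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        prob, truth = build_probability_map(cfg, rng)
        m = sample_matrix(prob, cfg.read_budget, rng, index=idx)
        out.append((m, truth))
    manifest = {"n_matrices": n, "config": cfg.manifest()}
    return out, manifest


def simulate_trans_map(n_foci: int = 28, *, size1: int = 160, size2: int = 160,
                       read_budget: int = 400_000, focus_intensity: float = 6.0,
                       focus_sigma: float = 1.8, min_separation: int = 12,
                       bin_size_bp: int = 2000, seed: int = 0
                       ) -> tuple[ContactMatrix, list[tuple[int, int]]]:
    """Two-chromosome map with focal patterns planted in the trans block.

    Emulates maps whose inter-chromosomal blocks carry recurring point-like
    patterns (e.g. clustered centromeres).  Intra blocks follow the default
    P(s) gradient; the trans block is uniform background with ``n_foci``
    Gaussian foci at random positions at least ``min_separation`` bins apart
    (Chebyshev) and clear of the block edge.  Returns the sampled matrix and
    the planted (global bin1, global bin2) truth list.
    """
    rng = np.random.default_rng(seed)
    idx = GenomeIndex(("chrA", "chrB"),
                      (size1 * bin_size_bp, size2 * bin_size_bp), bin_size_bp)
    n = idx.n_bins
    prob = np.zeros((n, n))
    for lo, hi, sz in ((0, size1, size1), (size1, n, size2)):
        ps = default_ps(sz)
        i, j = np.triu_indices(sz)
        blk = np.zeros((sz, sz))
        blk[i, j] = ps[j - i]
        prob[lo:hi, lo:hi] = blk

    trans = np.full((size1, size2), 0.02)
    margin = 9
    centres: list[tuple[int, int]] = []
    guard = 0
    while len(centres) < n_foci:
        guard += 1
        if guard > 100_000:
            raise RuntimeError("could not place the requested number of foci")
        r = int(rng.integers(margin, size1 - margin))
        c = int(rng.integers(margin, size2 - margin))
        if any(max(abs(r - a), abs(c - b)) < min_separation for a, b in centres):
            continue
        centres.append((r, c))
    gi, gj = np.mgrid[0:size1, 0:size2]
    for r, c in centres:
        trans += focus_intensity * 0.02 * np.exp(
            -((gi - r) ** 2 + (gj - c) ** 2) / (2.0 * focus_sigma ** 2))
    prob[0:size1, size1:n] = trans
    prob /= prob.sum()
    m = sample_matrix(prob, read_budget, rng, index=idx)
    truth = sorted((r, size1 + c) for r, c in centres)
    return m, truth
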