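"""Pattern templates (kernels) and their default detection parameters.

A kernel is a small odd-sized dense matrix encoding the visual signature of
a chromatin structure in an observed/expected map: a loop is a focal dot, a
domain border is a corner on the diagonal, a hairpin is a short stripe
perpendicular to the diagonal.  Kernels enter the pipeline only through a
Pearson correlation, which is invariant to affine rescaling, so every kernel
is stored standardised to mean 0 / SD 1.

Built-in kernels (``loops``, ``loops_small``, ``borders``, ``hairpins``) are
shipped as JSON files generated from noiseless simulator pileups by
``scripts/make_kernels.py``.  Users may supply their own kernels as JSON or
as a plain TSV matrix, or build one from windows picked on a real map with
:func:`kernel_from_windows`.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "Kernel",
    "KernelDefaults",
    "BUILTIN_KERNELS",
    "builtin_kernel",
    "load_kernel",
    "save_kernel",
    "kernel_from_windows",
    "tsvd_approximate",
]

BUILTIN_KERNELS = ("loops", "loops_small", "borders", "hairpins")

SYMMETRY_MODES = ("symmetric-pattern", "diagonal-pattern", "trans-pattern")


@dataclass(frozen=True)
class KernelDefaults:
    """Per-pattern default detection parameters.

    Distances are in bp so the same kernel serves any bin size; they are
    converted to bins against the map's resolution at run time.
    ``min_dist_bp = None`` means "kernel half-width + 1 bins" (the window
    must clear the diagonal mirror); ``max_dist_bp = None`` means no cap.
    """

    pearson_threshold: float = 0.35
    max_dist_bp: int | None = 2_000_000
    min_dist_bp: int | None = None
    min_separation_bins: int | None = None  # None -> kernel half-width
    max_empty_fraction: float = 0.3


@dataclass(frozen=True)
class Kernel:
    name: str
    matrix: np.ndarray
    defaults: KernelDefaults = field(default_factory=KernelDefaults)
    symmetry_mode: str = "diagonal-pattern"

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[0] % 2 == 0 or mat.shape[1] % 2 == 0:
            raise ValueError("kernel must be 2-D with odd dimensions")
        if not np.all(np.isfinite(mat)):
            raise ValueError("kernel contains non-finite values")
        if np.ptp(mat) == 0:
            raise ValueError("kernel has zero variance")
        if self.symmetry_mode not in SYMMETRY_MODES:
            raise ValueError(f"symmetry_mode must be one of {SYMMETRY_MODES}")
        object.__setattr__(self, "matrix", mat)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def half_width(self) -> int:
        return max(self.matrix.shape) // 2

    def standardised(self) -> "Kernel":
        mat = self.matrix
        return replace(self, matrix=(mat - mat.mean()) / mat.std())

    def with_defaults(self, **kw) -> "Kernel":
        return replace(self, defaults=replace(self.defaults, **kw))


def builtin_kernel(name: str) -> Kernel:
    """Load one of the shipped templates by name."""
    if name not in BUILTIN_KERNELS:
        raise KeyError(
            f"unknown kernel {name!r}; built-in kernels are: "
            + ", ".join(BUILTIN_KERNELS)
        )
    ref = resources.files("hicpat.data").joinpath(f"{name}.json")
    with ref.open() as fh:
        return _kernel_from_dict(json.load(fh))


def _kernel_from_dict(d: dict) -> Kernel:
    defaults = KernelDefaults(**d.get("defaults", {}))
    return Kernel(name=d["name"], matrix=np.asarray(d["matrix"], dtype=float),
                  defaults=defaults,
                  symmetry_mode=d.get("symmetry_mode", "diagonal-pattern"))


def load_kernel(path: str | Path, config_path: str | Path | None = None) -> Kernel:
    """Load a kernel from JSON, or from a TSV matrix plus optional JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            return _kernel_from_dict(json.load(fh))
    mat = np.loadtxt(path)
    cfg: dict = {}
    if config_path is not None:
        with open(config_path) as fh:
            cfg = json.load(fh)
    cfg.setdefault("name", path.stem)
    cfg["matrix"] = mat.tolist()
    return _kernel_from_dict(cfg)


def save_kernel(k: Kernel, path: str | Path) -> None:
    d = {
        "name": k.name,
        "matrix": [[round(float(v), 8) for v in row] for row in k.matrix],
        "defaults": asdict(k.defaults),
        "symmetry_mode": k.symmetry_mode,
    }
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)
        fh.write("\n")


def kernel_from_windows(windows, gaussian_sigma: float = 1.0,
                        name: str = "custom",
                        symmetry_mode: str = "trans-pattern",
                        defaults: KernelDefaults | None = None) -> Kernel:
    """Build a kernel from map windows centred on user-picked coordinates.

    The windows (equal odd shapes, typically cut from a detrended map around
    hand-selected pattern occurrences) are summed, smoothed with a Gaussian
    filter of width ``gaussian_sigma`` (``0`` disables smoothing), and
    standardised.  Cells that are NaN in some windows (masked pixels) are
    averaged over the windows where they are observed.
    """
    stack = [np.asarray(w, dtype=float) for w in windows]
    if len(stack) == 0:
        raise ValueError("at least one window is required")
    shape = stack[0].shape
    if any(w.shape != shape for w in stack):
        raise ValueError("windows have mixed shapes")
    if shape[0] % 2 == 0 or shape[1] % 2 == 0:
        raise ValueError("windows must have odd dimensions")
    arr = np.stack(stack)
    counts = np.isfinite(arr).sum(axis=0)
    if np.any(counts == 0):
        raise ValueError("some window cells are masked in every window")
    # exact per-cell summation: the kernel is identical for any window order
    total = np.empty(shape)
    for i in range(shape[0]):
        for j in range(shape[1]):
            total[i, j] = math.fsum(v for v in arr[:, i, j] if np.isfinite(v))
    total *= len(stack) / counts
    if gaussian_sigma > 0:
        total = gaussian_filter(total, sigma=gaussian_sigma, mode="nearest")
    kern = Kernel(name=name, matrix=total,
                  defaults=defaults or KernelDefaults(),
                  symmetry_mode=symmetry_mode)
    return kern.standardised()


def tsvd_approximate(k: Kernel, rank: int) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Truncated SVD factorisation of a kernel into rank-1 terms.

    Returns ``[(sigma, u, v), ...]`` such that ``sum(sigma * outer(u, v))``
    reconstructs the kernel with squared Frobenius error equal to the energy
    of the discarded singular values.  The factors let the correlation stage
    replace one 2-D convolution by ``rank`` separable (column then row) 1-D
    convolutions.
    """
    m, n = k.shape
    if not 1 <= rank <= min(m, n):
        raise ValueError(f"rank must be in [1, {min(m, n)}]")
    u, s, vt = np.linalg.svd(k.matrix, full_matrices=False)
    return [(float(s[r]), u[:, r].copy(), vt[r, :].copy()) for r in range(rank)]


def reconstruct_tsvd(factors) -> np.ndarray:
    out = None
    for sigma, u, v in factors:
        term = sigma * np.outer(u, v)
        out = term if out is None else out + term
    return out
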