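"""Generate the built-in pattern kernels shipped with the package.

Each kernel is the detrended pileup of its pattern as planted by the
synthetic-map generator: a noiseless probability map is built with the
pattern's template, converted to observed/expected by dividing each
diagonal (or the trans block) by its mean, and windows centred on the
planted truth coordinates are averaged, smoothed and standardised.  This is
the same pileup-as-template logic users apply when deriving a custom kernel
from windows picked on a real map.

Run from the repository root:

    python scripts/make_kernels.py

Writes JSON kernels into src/hicpat/data/.
"""

from pathlib import Path

import numpy as np

from hicpat.kernels import Kernel, KernelDefaults, kernel_from_windows, save_kernel
from hicpat.simulate import (SimConfig, border_template, build_probability_map,
                             hairpin_template, loop_template)

OUT = Path(__file__).resolve().parents[1] / "src" / "hicpat" / "data"
RADIUS = 8  # 17 x 17 pileups


def detrended(prob: np.ndarray) -> np.ndarray:
    """Observed/expected of a noiseless upper-triangular probability map."""
    n = prob.shape[0]
    sym = prob + np.triu(prob, k=1).T
    out = np.zeros_like(sym)
    for s in range(n):
        diag = np.diagonal(sym, offset=s)
        mean = diag.mean()
        if mean > 0:
            idx = np.arange(n - s)
            out[idx, idx + s] = diag / mean
            out[idx + s, idx] = diag / mean
    return out


def pileup_kernel(cfg: SimConfig, centres, name: str,
                  defaults: KernelDefaults, sigma: float = 1.0) -> Kernel:
    prob, _ = build_probability_map(cfg, seed=cfg.seed)
    oe = detrended(prob)
    n = prob.shape[0]
    wins = []
    for r, c in centres:
        if RADIUS <= r < n - RADIUS and RADIUS <= c < n - RADIUS:
            wins.append(oe[r - RADIUS:r + RADIUS + 1, c - RADIUS:c + RADIUS + 1])
    kern = kernel_from_windows(wins, gaussian_sigma=sigma, name=name,
                               symmetry_mode="diagonal-pattern",
                               defaults=defaults)
    return kern


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # loops: pileup of planted loop positions on a borders+loops map
    cfg = SimConfig(seed=7, loop_probability=1.0)
    prob, truth = build_probability_map(cfg, seed=cfg.seed)
    oe = detrended(prob)
    n = prob.shape[0]
    wins = [oe[r - RADIUS:r + RADIUS + 1, c - RADIUS:c + RADIUS + 1]
            for r, c in truth.loops
            if RADIUS <= r < n - RADIUS and RADIUS <= c < n - RADIUS]
    loops = kernel_from_windows(
        wins, gaussian_sigma=1.0, name="loops",
        symmetry_mode="diagonal-pattern",
        defaults=KernelDefaults(pearson_threshold=0.35, max_dist_bp=2_000_000))
    save_kernel(loops, OUT / "loops.json")

    small = Kernel(name="loops_small",
                   matrix=loops.matrix[RADIUS - 3:RADIUS + 4,
                                       RADIUS - 3:RADIUS + 4],
                   defaults=KernelDefaults(pearson_threshold=0.35,
                                           max_dist_bp=2_000_000),
                   symmetry_mode="diagonal-pattern").standardised()
    save_kernel(small, OUT / "loops_small.json")

    # borders: pileup at planted border positions (no loops in the map)
    cfg_b = SimConfig(seed=11, loop_probability=0.0,
                      border_tpl=border_template())
    prob, truth = build_probability_map(cfg_b, seed=cfg_b.seed)
    oe = detrended(prob)
    wins = [oe[b - RADIUS:b + RADIUS + 1, b - RADIUS:b + RADIUS + 1]
            for b in truth.borders if RADIUS <= b < n - RADIUS]
    borders = kernel_from_windows(
        wins, gaussian_sigma=1.0, name="borders",
        symmetry_mode="diagonal-pattern",
        defaults=KernelDefaults(pearson_threshold=0.4, max_dist_bp=50_000,
                                min_dist_bp=0))
    save_kernel(borders, OUT / "borders.json")

    # hairpins: pileup of hairpin templates planted in place of borders
    cfg_h = SimConfig(seed=13, loop_probability=0.0,
                      border_tpl=hairpin_template())
    prob, truth = build_probability_map(cfg_h, seed=cfg_h.seed)
    oe = detrended(prob)
    wins = [oe[b - RADIUS:b + RADIUS + 1, b - RADIUS:b + RADIUS + 1]
            for b in truth.borders if RADIUS <= b < n - RADIUS]
    hairpins = kernel_from_windows(
        wins, gaussian_sigma=1.0, name="hairpins",
        symmetry_mode="diagonal-pattern",
        defaults=KernelDefaults(pearson_threshold=0.4, max_dist_bp=100_000,
                                min_dist_bp=0))
    save_kernel(hairpins, OUT / "hairpins.json")

    for k in ("loops", "loops_small", "borders", "hairpins"):
        print(f"wrote {OUT / (k + '.json')}")


if __name__ == "__main__":
    main()
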