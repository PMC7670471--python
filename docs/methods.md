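# Methods

## Model

`hicpat` scores how much each neighbourhood of an observed/expected Hi-C
map resembles a template. For a kernel `K` (odd dimensions `M×N`) and a
map window `W` centred on bin pair `(i, j)`, the score is the Pearson
correlation computed over the set `V` of *valid* pixels — positions whose
bin row and column are not masked:

```
corr(i,j) = Σ_V (W−mean_V W)(K−mean_V K) / sqrt(Σ_V (W−mean_V W)² · Σ_V (K−mean_V K)²)
```

Structural zeros at valid bins are data (a detrended zero is a real
observed/expected value); only masked-bin pixels leave `V`. Windows
truncated by the matrix edge are not scored at all — zero-padding would
bias both means — and a centre is masked when more than a configurable
fraction of its window is invalid (default 0.3, applied both at correlation
and again at the final filtering step) or when either factor is constant on
`V` (the coefficient is undefined there, and reporting 0 would conflate
"no evidence" with "evidence of absence").

The implementation writes the per-window sums as cross-correlations of the
masked image with the kernel, its square and a box filter, evaluated by
direct (non-FFT) convolution on per-block dense arrays restricted to the
scan band, in row tiles so memory stays bounded on large chromosomes. The
contract is equality with a brute-force dense evaluation of the formula
above; the test suite enforces agreement to 1e-10 on random masked
fixtures. An optional truncated-SVD path replaces the kernel-shaped
correlations by separable rank-1 passes; it factors the kernel *as
supplied* (standardising first would raise the rank of exactly separable
templates) and is exact at full rank.

Assumptions: the map is symmetric and analysed per chromosome
(diagonal-band patterns) or per chromosome pair (trans patterns); balancing
is genome-wide; detrending is per chromosome, each diagonal divided by its
mean over valid positions (pooling `P(s)` across chromosomes would mix
chromosome-specific decay; the per-chromosome choice is the default and the
only implemented variant). Trans blocks are detrended by their block mean,
as they have no distance decay.

## Detection

Centres with `corr ≥ τ` form the nodes of a sparse adjacency graph (edges
between 4-connected pixels); connected components are correlation foci.
Foci with fewer than two pixels are discarded as speckle. Each focus
contributes its argmax (ties broken toward the lexicographically smallest
bin pair, for determinism). Candidates are then scanned by decreasing
score; a candidate within a Chebyshev radius (default: kernel half-width)
of an accepted one is dropped, as are candidates whose window overlaps too
many masked pixels. Everything is deterministic: identical inputs and
parameters give byte-identical outputs.

Scanning geometry per kernel symmetry mode: diagonal-pattern kernels scan
the upper-triangle band between a minimum distance (default: kernel
half-width + 1, so windows never straddle the diagonal mirror) and a
maximum distance (loops default 2 Mb, converted to bins at run time);
trans-pattern kernels scan whole inter-chromosomal blocks. Only the upper
triangle is scanned; mirror-image foci are not merged because they cannot
arise there.

No statistical significance is attached to calls: the method is
correlation-thresholded by design, and the score itself is the quantity
users threshold, sweep, or compare between conditions.

## Kernels

Kernels enter only through the Pearson coefficient, which is invariant to
affine rescaling, so all kernels are stored standardised (mean 0, SD 1).
The built-ins (`loops` 17×17, `loops_small` its central 7×7 crop — the
small variant tolerates calls closer to the diagonal, `borders`,
`hairpins`) are generated by `scripts/make_kernels.py` as detrended pileups
of the corresponding planted pattern in a noiseless simulator probability
map — the same pileup-as-template logic a user applies when deriving a
custom kernel from picked windows. They are documented equivalents of the
patterns they represent, not copies of any particular experimental pileup.

`kernel_from_windows` builds a template de novo: equal-shaped windows cut
around hand-picked coordinates are summed (per-cell exact summation, so
the result is independent of window order; cells masked in some windows
are averaged over the windows that observe them), Gaussian-smoothed
(σ = 1 bin by default; σ = 0 disables smoothing) and standardised.

Default thresholds per kernel — loops 0.35, borders 0.40, hairpins 0.40 —
are starting points meant to be swept; the benchmark module exists
precisely to pick them on labelled data.

## Preprocessing parameters

- ICE balancing: multiplicative bias updates until the coefficient of
  variation of valid-bin marginals falls below `tol` (default 1e-5, max 300
  iterations; non-convergence warns and returns the last iterate). The
  balanced matrix is scaled so valid marginals average 1.
- Missing bins: a bin is invalid when its nonzero-pixel count falls below
  median − 3·MAD of per-bin counts (robust to the heavy tail of
  well-covered bins) or has no contacts at all. The multiplier is
  configurable.
- Detrending: diagonals with zero mean are left untouched; pixels beyond
  the maximum scan distance are dropped at this stage, which commutes with
  detrending for the retained diagonals.

## Synthetic data

The generator emulates a mitotic yeast chromosome binned at 2 kb. Defaults:
289×289 bins; `P(s) ∝ s^(−1.5)` (a generic polymer-decay slope; any
empirical table can be supplied instead); border templates placed on the
diagonal at spacings drawn from Normal(20, 8) bins truncated at ≥ 6; loop
templates planted on border pairs 2–100 bins apart, each pair used with
probability 0.5; the product of the three factor maps is normalised and
sampled multinomially at 500,000 contacts per matrix — a realistic intra-
chromosomal depth for a well-covered yeast chromosome. Analytic templates
stand in for experimental pileups: a Gaussian dot (intensity 3, σ 1.8 bins)
for loops, an insulation corner (same-side enrichment e^0.8, cross-boundary
depletion e^−0.8, reach 5 bins) for borders, an anti-diagonal stripe for
hairpins. All stand-ins are configuration, not code: supplying empirical
`P(s)` tables and pileup templates reproduces a specific experiment's
conditions.

What the simulator does *not* emulate: translocation/repeat artefacts,
copy-number variation, distance-dependent noise correlations, or
experimental white lines (masking is exercised separately in unit
fixtures). Passing benchmarks on these maps therefore demonstrates
correctness of the machinery and realistic sensitivity under multinomial
counting noise, not performance on every pathology of real libraries.

`simulate_trans_map` extends the same sampling scheme to a two-chromosome
genome with Gaussian foci planted in the inter-chromosomal block, providing
labelled truth for trans-pattern detection and for the
kernel-from-windows workflow.

## Benchmarking

Detections and truth points are matched one-to-one within a Chebyshev
tolerance (default 2 bins — focus maxima can shift a pixel or two under
counting noise) by maximum-cardinality bipartite matching (augmenting
paths, closer pairs preferred), so the TP count never depends on scan
order. Metrics are micro-averaged over the matrix ensemble: precision
TP/(TP+FP), sensitivity TP/(TP+FN), F1 their harmonic mean; undefined
ratios are reported as 0 with an explicit flag. `parameter_sweep` evaluates
a threshold × separation grid while computing each matrix's correlation map
once, and flags the best-F1 row (ties broken toward the smallest
parameters, making the choice grid-order invariant).

The shipped acceptance run uses 50 simulated matrices; that ensemble size
gives the pooled sensitivity a standard error of about one percentage
point, stable across master seeds.

## Quantification

`quantify` scores supplied coordinates with the identical code path used by
detection (bit-for-bit agreement is a tested invariant); unscorable rows
are flagged (`edge`, `masked`, `undefined`, `out-of-range`), never silently
dropped. `pileup` averages observed/expected windows per cell over valid
pixels with exact summation (order-invariant); radius 8 gives the
conventional 17×17 aggregate. `loop_spectrum` scores all intra-chromosomal
anchor pairs up to a maximum separation (default 1 Mb), buckets scores by
pair distance (default 2-bin buckets; the bucket width is a logged
parameter), and reports per-bucket means with a seeded 1000-resample
bootstrap 95% CI; lowess smoothing (fraction 0.3) is available for plots
but never alters the exported table.

## Numerical choices and degenerate inputs

- Variance guard: a window counts as constant when its centred sum of
  squares is below 1e-12 of its raw sum of squares; such centres are
  masked, not scored 0.
- All-zero matrices balance to an error, detect to an empty list.
- Equal-score ties anywhere (focus argmax, greedy scan, best grid row)
  break lexicographically.
- Coordinates are 0-based bins internally; genomic intervals are 0-based
  half-open (BED convention). Only the upper triangle is stored; all query
  APIs are symmetric.

## Known limitations

- cool support covers single-resolution fixed-bin containers; mcool
  pyramids and Juicer .hic files are out of scope (open one resolution with
  external tooling first).
- Scanning cost grows with band area; very large maps at fine resolution
  rely on the row-tiled path and a sensible maximum distance.
- Alternative normalisations (KR, VC) and significance/FDR models are
  deliberately absent.
- The simulator's analytic templates are smooth idealisations; detection
  thresholds tuned on them should be re-swept on real data.
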