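"""Loop spectrum: kernel score of anchor pairs vs their separation.

Simulates a map whose loops connect anchors exactly 20 bins (40 kb) apart,
then scores every intra-chromosomal anchor pair by distance: the spectrum
peaks at the planted size.
"""

import hicpat as hp

cfg = hp.SimConfig(seed=5, border_spacing_sd=0.0, border_spacing_mean=20.0,
                   loop_min_dist=18, loop_max_dist=22, loop_probability=1.0)
dataset, _ = hp.simulate_dataset(cfg, n_matrices=1)
matrix, truth = dataset[0]
kernel = hp.builtin_kernel("loops")

anchors = [("chrS", b * 2000 + 1000) for b in truth.borders]
spectrum = hp.loop_spectrum(matrix, anchors, kernel,
                            max_dist_bp=130 * 2000, bucket_width_bins=2,
                            seed=0)
print(spectrum.to_string(index=False,
                         formatters={"mean_score": "{:.3f}".format,
                                     "ci_lo": "{:.3f}".format,
                                     "ci_hi": "{:.3f}".format}))
peak = spectrum.loc[spectrum["mean_score"].idxmax()]
print(f"peak at {peak.distance_bp / 1000:.0f} kb "
      f"(planted loop size 40 kb): the spectrum recovers the characteristic "
      "loop size; other buckets hold anchor pairs without a planted loop.")
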