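"""Parameter sweep of the detector on a labelled synthetic ensemble.

Generates 10 labelled matrices, evaluates a grid of detection thresholds
and separation radii, and reports pooled precision/sensitivity/F1 per
combination.
"""

import hicpat as hp

cfg = hp.SimConfig(seed=2)
dataset, _ = hp.simulate_dataset(cfg, n_matrices=10)
kernel = hp.builtin_kernel("loops")

table = hp.parameter_sweep(dataset, kernel, tolerance_bins=2)
print(table.to_string(index=False, float_format="%.3f"))
best = table[table["best"]].iloc[0]
print(f"best F1 {best.f1:.3f} at pearson={best.pearson}, "
      f"min_separation={best.min_separation_bins} bins")
print("Lower thresholds trade precision for sensitivity; the flagged row "
      "is the combination a user would pick for this data.")
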