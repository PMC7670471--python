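{
 "name": "loops_small",
 "matrix": [
  [
   -1.46456444,
   -1.05437727,
   -0.64948433,
   -0.45773196,
   -0.59088902,
   -0.95891926,
   -1.35788799
  ],
  [
   -1.04600048,
   -0.32425919,
   0.37745452,
   0.6937386,
   0.43347154,
   -0.23844027,
   -0.95891865
  ],
  [
   -0.62869704,
   0.39110666,
   1.36860527,
   1.79048775,
   1.39821703,
   0.43347159,
   -0.5908881
  ],
  [
   -0.42322513,
   0.72326868,
   1.80826183,
   2.25641129,
   1.79048775,
   0.69373865,
   -0.45773089
  ],
  [
   -0.54621701,
   0.47576048,
   1.43181801,
   1.80826183,
   1.36860527,
   0.37745457,
   -0.64948335
  ],
  [
   -0.91128747,
   -0.19065922,
   0.47576043,
   0.72326863,
   0.39110661,
   -0.32425918,
   -1.05437659
  ],
  [
   -1.31246463,
   -0.9112881,
   -0.54621793,
   -0.42322614,
   -0.62869792,
   -1.04600106,
   -1.46456438
  ]
 ],
 "defaults": {
  "pearson_threshold": 0.35,
  "max_dist_bp": 2000000,
  "min_dist_bp": null,
  "min_separation_bins": null,
  "max_empty_fraction": 0.3
 },
 "symmetry_mode": "diagonal-pattern"
}
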