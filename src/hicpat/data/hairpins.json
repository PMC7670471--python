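{
 "name": "hairpins",
 "matrix": [
  [
   -0.8181567,
   -0.74713858,
   -0.63830343,
   -0.54336909,
   -0.52248208,
   -0.58344822,
   -0.67194428,
   -0.730654,
   -0.74410692,
   -0.72406029,
   -0.67440234,
   -0.57172465,
   -0.37200576,
   -0.05855654,
   0.28782864,
   0.51135726,
   0.56311216
  ],
  [
   -0.74713858,
   -0.66814916,
   -0.57941534,
   -0.54105114,
   -0.57851913,
   -0.66137214,
   -0.735704,
   -0.77018894,
   -0.76347212,
   -0.71601174,
   -0.60236316,
   -0.37338424,
   -0.00892607,
   0.40398333,
   0.6747256,
   0.67269749,
   0.51135726
  ],
  [
   -0.63830343,
   -0.57941534,
   -0.54781422,
   -0.58521194,
   -0.67084118,
   -0.75388037,
   -0.80036166,
   -0.80354887,
   -0.75826583,
   -0.62961963,
   -0.35118808,
   0.11227475,
   0.65871752,
   1.03583555,
   1.02596113,
   0.6747256,
   0.28782864
  ],
  [
   -0.54336909,
   -0.54105114,
   -0.58521194,
   -0.67474149,
   -0.76561235,
   -0.82223961,
   -0.83457321,
   -0.79317106,
   -0.65354328,
   -0.32959869,
   0.2357633,
   0.934461,
   1.45374963,
   1.4889838,
   1.03583555,
   0.40398333,
   -0.05855654
  ],
  [
   -0.52248208,
   -0.57851913,
   -0.67084118,
   -0.76561235,
   -0.82949882,
   -0.8503735,
   -0.81501933,
   -0.67028563,
   -0.31115487,
   0.34426487,
   1.19078884,
   1.86377462,
   1.96938018,
   1.45374963,
   0.65871752,
   -0.00892607,
   -0.37200576
  ],
  [
   -0.58344822,
   -0.66137214,
   -0.75388037,
   -0.82223961,
   -0.8503735,
   -0.82211326,
   -0.67822068,
   -0.2979284,
   0.42577866,
   1.3996576,
   2.22181174,
   2.41478382,
   1.86377462,
   0.934461,
   0.11227475,
   -0.37338424,
   -0.57172465
  ],
  [
   -0.67194428,
   -0.735704,
   -0.80036166,
   -0.83457321,
   -0.81501933,
   -0.67822068,
   -0.29274725,
   0.47041475,
   1.53742348,
   2.48823012,
   2.77696078,
   2.22181174,
   1.19078884,
   0.2357633,
   -0.35118808,
   -0.60236316,
   -0.67440234
  ],
  [
   -0.730654,
   -0.77018894,
   -0.80354887,
   -0.79317106,
   -0.67028563,
   -0.2979284,
   0.47041475,
   1.58616915,
   2.63178795,
   3.01499077,
   2.48823012,
   1.3996576,
   0.34426487,
   -0.32959869,
   -0.62961963,
   -0.71601174,
   -0.72406029
  ],
  [
   -0.74410692,
   -0.76347212,
   -0.75826583,
   -0.65354328,
   -0.31115487,
   0.42577866,
   1.53742348,
   2.63178795,
   3.09881586,
   2.63178795,
   1.53742348,
   0.42577866,
   -0.31115487,
   -0.65354328,
   -0.75826583,
   -0.76347212,
   -0.74410692
  ],
  [
   -0.72406029,
   -0.71601174,
   -0.62961963,
   -0.32959869,
   0.34426487,
   1.3996576,
   2.48823012,
   3.01499077,
   2.63178795,
   1.58616915,
   0.47041475,
   -0.2979284,
   -0.67028563,
   -0.79317106,
   -0.80354887,
   -0.77018894,
   -0.730654
  ],
  [
   -0.67440234,
   -0.60236316,
   -0.35118808,
   0.2357633,
   1.19078884,
   2.22181174,
   2.77696078,
   2.48823012,
   1.53742348,
   0.47041475,
   -0.29274725,
   -0.67822068,
   -0.81501933,
   -0.83457321,
   -0.80036166,
   -0.735704,
   -0.67194428
  ],
  [
   -0.57172465,
   -0.37338424,
   0.11227475,
   0.934461,
   1.86377462,
   2.41478382,
   2.22181174,
   1.3996576,
   0.42577866,
   -0.2979284,
   -0.67822068,
   -0.82211326,
   -0.8503735,
   -0.82223961,
   -0.75388037,
   -0.66137214,
   -0.58344822
  ],
  [
   -0.37200576,
   -0.00892607,
   0.65871752,
   1.45374963,
   1.96938018,
   1.86377462,
   1.19078884,
   0.34426487,
   -0.31115487,
   -0.67028563,
   -0.81501933,
   -0.8503735,
   -0.82949882,
   -0.76561235,
   -0.67084118,
   -0.57851913,
   -0.52248208
  ],
  [
   -0.05855654,
   0.40398333,
   1.03583555,
   1.4889838,
   1.45374963,
   0.934461,
   0.2357633,
   -0.32959869,
   -0.65354328,
   -0.79317106,
   -0.83457321,
   -0.82223961,
   -0.76561235,
   -0.67474149,
   -0.58521194,
   -0.54105114,
   -0.54336909
  ],
  [
   0.28782864,
   0.6747256,
   1.02596113,
   1.03583555,
   0.65871752,
   0.11227475,
   -0.35118808,
   -0.62961963,
   -0.75826583,
   -0.80354887,
   -0.80036166,
   -0.75388037,
   -0.67084118,
   -0.58521194,
   -0.54781422,
   -0.57941534,
   -0.63830343
  ],
  [
   0.51135726,
   0.67269749,
   0.6747256,
   0.40398333,
   -0.00892607,
   -0.37338424,
   -0.60236316,
   -0.71601174,
   -0.76347212,
   -0.77018894,
   -0.735704,
   -0.66137214,
   -0.57851913,
   -0.54105114,
   -0.57941534,
   -0.66814916,
   -0.74713858
  ],
  [
   0.56311216,
   0.51135726,
   0.28782864,
   -0.05855654,
   -0.37200576,
   -0.57172465,
   -0.67440234,
   -0.72406029,
   -0.74410692,
   -0.730654,
   -0.67194428,
   -0.58344822,
   -0.52248208,
   -0.54336909,
   -0.63830343,
   -0.74713858,
   -0.8181567
  ]
 ],
 "defaults": {
  "pearson_threshold": 0.4,
  "max_dist_bp": 100000,
  "min_dist_bp": 0,
  "min_separation_bins": null,
  "max_empty_fraction": 0.3
 },
 "symmetry_mode": "diagonal-pattern"
}
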