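{
 "name": "borders",
 "matrix": [
  [
   -0.54990894,
   -0.46707075,
   -0.33546157,
   -0.08769829,
   0.29030656,
   0.71074204,
   1.0273823,
   0.95484661,
   0.35800196,
   -0.2963454,
   -0.57829184,
   -0.59574057,
   -0.54884587,
   -0.48782856,
   -0.41538913,
   -0.34104173,
   -0.2849323
  ],
  [
   -0.46707075,
   -0.4411792,
   -0.33864319,
   -0.07634062,
   0.3382019,
   0.80907504,
   1.17079965,
   1.0696782,
   0.34572967,
   -0.41868049,
   -0.72452236,
   -0.72664694,
   -0.66195767,
   -0.58454473,
   -0.49645669,
   -0.40766231,
   -0.34104173
  ],
  [
   -0.33546157,
   -0.33864319,
   -0.23058657,
   0.06612854,
   0.51691854,
   1.03567335,
   1.43974443,
   1.27579672,
   0.34759586,
   -0.59231767,
   -0.94220071,
   -0.92142634,
   -0.82407404,
   -0.71786896,
   -0.60573071,
   -0.49645669,
   -0.41538913
  ],
  [
   -0.08769829,
   -0.07634062,
   0.06612854,
   0.37823718,
   0.80798705,
   1.3190775,
   1.72967514,
   1.47546999,
   0.31746496,
   -0.81377884,
   -1.21329733,
   -1.16226576,
   -1.01448314,
   -0.86307411,
   -0.71786896,
   -0.58454473,
   -0.48782856
  ],
  [
   0.29030656,
   0.3382019,
   0.51691854,
   0.80798705,
   1.14401876,
   1.56037715,
   1.91406761,
   1.55423827,
   0.1960319,
   -1.08828953,
   -1.52110769,
   -1.43470748,
   -1.22651754,
   -1.01448314,
   -0.82407404,
   -0.66195767,
   -0.54884587
  ],
  [
   0.71074204,
   0.80907504,
   1.03567335,
   1.3190775,
   1.56037715,
   1.82699092,
   2.03920888,
   1.5361372,
   0.01465176,
   -1.36931699,
   -1.81435081,
   -1.69580732,
   -1.43470748,
   -1.16226576,
   -0.92142634,
   -0.72664694,
   -0.59574057
  ],
  [
   1.0273823,
   1.17079965,
   1.43974443,
   1.72967514,
   1.91406761,
   2.03920888,
   2.05899452,
   1.39733437,
   -0.18564174,
   -1.55009965,
   -1.96109658,
   -1.81435081,
   -1.52110769,
   -1.21329733,
   -0.94220071,
   -0.72452236,
   -0.57829184
  ],
  [
   0.95484661,
   1.0696782,
   1.27579672,
   1.47546999,
   1.55423827,
   1.5361372,
   1.39733437,
   0.77357763,
   -0.41931533,
   -1.34139349,
   -1.55009965,
   -1.36931699,
   -1.08828953,
   -0.81377884,
   -0.59231767,
   -0.41868049,
   -0.2963454
  ],
  [
   0.35800196,
   0.34572967,
   0.34759586,
   0.31746496,
   0.1960319,
   0.01465176,
   -0.18564174,
   -0.41931533,
   -0.55703861,
   -0.41931533,
   -0.18564174,
   0.01465176,
   0.1960319,
   0.31746496,
   0.34759586,
   0.34572967,
   0.35800196
  ],
  [
   -0.2963454,
   -0.41868049,
   -0.59231767,
   -0.81377884,
   -1.08828953,
   -1.36931699,
   -1.55009965,
   -1.34139349,
   -0.41931533,
   0.77357763,
   1.39733437,
   1.5361372,
   1.55423827,
   1.47546999,
   1.27579672,
   1.0696782,
   0.95484661
  ],
  [
   -0.57829184,
   -0.72452236,
   -0.94220071,
   -1.21329733,
   -1.52110769,
   -1.81435081,
   -1.96109658,
   -1.55009965,
   -0.18564174,
   1.39733437,
   2.05899452,
   2.03920888,
   1.91406761,
   1.72967514,
   1.43974443,
   1.17079965,
   1.0273823
  ],
  [
   -0.59574057,
   -0.72664694,
   -0.92142634,
   -1.16226576,
   -1.43470748,
   -1.69580732,
   -1.81435081,
   -1.36931699,
   0.01465176,
   1.5361372,
   2.03920888,
   1.82699092,
   1.56037715,
   1.3190775,
   1.03567335,
   0.80907504,
   0.71074204
  ],
  [
   -0.54884587,
   -0.66195767,
   -0.82407404,
   -1.01448314,
   -1.22651754,
   -1.43470748,
   -1.52110769,
   -1.08828953,
   0.1960319,
   1.55423827,
   1.91406761,
   1.56037715,
   1.14401876,
   0.80798705,
   0.51691854,
   0.3382019,
   0.29030656
  ],
  [
   -0.48782856,
   -0.58454473,
   -0.71786896,
   -0.86307411,
   -1.01448314,
   -1.16226576,
   -1.21329733,
   -0.81377884,
   0.31746496,
   1.47546999,
   1.72967514,
   1.3190775,
   0.80798705,
   0.37823718,
   0.06612854,
   -0.07634062,
   -0.08769829
  ],
  [
   -0.41538913,
   -0.49645669,
   -0.60573071,
   -0.71786896,
   -0.82407404,
   -0.92142634,
   -0.94220071,
   -0.59231767,
   0.34759586,
   1.27579672,
   1.43974443,
   1.03567335,
   0.51691854,
   0.06612854,
   -0.23058657,
   -0.33864319,
   -0.33546157
  ],
  [
   -0.34104173,
   -0.40766231,
   -0.49645669,
   -0.58454473,
   -0.66195767,
   -0.72664694,
   -0.72452236,
   -0.41868049,
   0.34572967,
   1.0696782,
   1.17079965,
   0.80907504,
   0.3382019,
   -0.07634062,
   -0.33864319,
   -0.4411792,
   -0.46707075
  ],
  [
   -0.2849323,
   -0.34104173,
   -0.41538913,
   -0.48782856,
   -0.54884587,
   -0.59574057,
   -0.57829184,
   -0.2963454,
   0.35800196,
   0.95484661,
   1.0273823,
   0.71074204,
   0.29030656,
   -0.08769829,
   -0.33546157,
   -0.46707075,
   -0.54990894
  ]
 ],
 "defaults": {
  "pearson_threshold": 0.4,
  "max_dist_bp": 50000,
  "min_dist_bp": 0,
  "min_separation_bins": null,
  "max_empty_fraction": 0.3
 },
 "symmetry_mode": "diagonal-pattern"
}
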