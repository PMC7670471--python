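{
 "name": "loops",
 "matrix": [
  [
   -0.6055153,
   -0.59477995,
   -0.57458087,
   -0.54593187,
   -0.51304661,
   -0.48194338,
   -0.45574818,
   -0.43625379,
   -0.42572615,
   -0.42503104,
   -0.43250703,
   -0.44507017,
   -0.45990683,
   -0.47487421,
   -0.48796319,
   -0.49726957,
   -0.50205705
  ],
  [
   -0.60128026,
   -0.59699586,
   -0.58480455,
   -0.56207316,
   -0.53102387,
   -0.49788451,
   -0.46690603,
   -0.44158086,
   -0.42598651,
   -0.42186111,
   -0.42718402,
   -0.43804679,
   -0.45134794,
   -0.46543874,
   -0.47901577,
   -0.49026048,
   -0.4972599
  ],
  [
   -0.58852762,
   -0.59179049,
   -0.5899057,
   -0.57529347,
   -0.54529229,
   -0.50362487,
   -0.45555014,
   -0.41092173,
   -0.38316601,
   -0.37916324,
   -0.39368761,
   -0.41509806,
   -0.43501114,
   -0.45160873,
   -0.46618621,
   -0.47899283,
   -0.48791518
  ],
  [
   -0.56683409,
   -0.57516614,
   -0.58096368,
   -0.57067531,
   -0.53151611,
   -0.45822188,
   -0.35675927,
   -0.2559897,
   -0.19933643,
   -0.21039189,
   -0.27205672,
   -0.34458392,
   -0.39942994,
   -0.43217794,
   -0.45158373,
   -0.46535042,
   -0.47470009
  ],
  [
   -0.54023356,
   -0.54913348,
   -0.55516107,
   -0.53541578,
   -0.45720449,
   -0.29485207,
   -0.05663038,
   0.18152324,
   0.3024019,
   0.24200264,
   0.04887742,
   -0.16480798,
   -0.31826332,
   -0.39941627,
   -0.43493554,
   -0.45109395,
   -0.45940814
  ],
  [
   -0.51318099,
   -0.51786291,
   -0.51345371,
   -0.46074273,
   -0.29237373,
   0.05321881,
   0.55997417,
   1.0601889,
   1.29708451,
   1.13257899,
   0.67790535,
   0.18500954,
   -0.16480369,
   -0.34455108,
   -0.41492504,
   -0.43746848,
   -0.44393628
  ],
  [
   -0.48522427,
   -0.4832275,
   -0.45965322,
   -0.35179343,
   -0.04498812,
   0.57032307,
   1.46198007,
   2.32889452,
   2.71963967,
   2.39809932,
   1.56800289,
   0.67790611,
   0.04888564,
   -0.27199667,
   -0.39337362,
   -0.42613794,
   -0.43045884
  ],
  [
   -0.44289879,
   -0.43788612,
   -0.39738306,
   -0.2351081,
   0.20784328,
   1.08587004,
   2.34576071,
   3.55338663,
   4.07459066,
   3.58996972,
   2.39809938,
   1.13258014,
   0.24201464,
   -0.21030485,
   -0.37871046,
   -0.42035726,
   -0.42209059
  ],
  [
   -0.37746673,
   -0.37799546,
   -0.3357053,
   -0.15303676,
   0.34714162,
   1.33971511,
   2.75612187,
   4.0965492,
   4.65020411,
   4.07459066,
   2.71963975,
   1.29708584,
   0.30241575,
   -0.19923634,
   -0.38264738,
   -0.42426844,
   -0.42237094
  ],
  [
   -0.3242731,
   -0.33258402,
   -0.30135321,
   -0.14270951,
   0.30076652,
   1.1877679,
   2.45034413,
   3.6314812,
   4.0965492,
   3.55338663,
   2.32889458,
   1.06019011,
   0.18153587,
   -0.25589855,
   -0.41045038,
   -0.4400221,
   -0.43321245
  ],
  [
   -0.32279113,
   -0.33161175,
   -0.31147532,
   -0.20104074,
   0.11017003,
   0.73675085,
   1.62703277,
   2.45034407,
   2.75612181,
   2.34576065,
   1.46198008,
   0.55997501,
   -0.05662133,
   -0.35669366,
   -0.45521076,
   -0.4657844,
   -0.4535607
  ],
  [
   -0.3575641,
   -0.36116929,
   -0.34711132,
   -0.28320123,
   -0.10908182,
   0.24112668,
   0.73675006,
   1.18776676,
   1.33971386,
   1.08586895,
   0.57032234,
   0.05321888,
   -0.29484713,
   -0.45818467,
   -0.5034317,
   -0.49724565,
   -0.48069729
  ],
  [
   -0.39913307,
   -0.39646973,
   -0.38333502,
   -0.34847699,
   -0.26719227,
   -0.10908663,
   0.11016118,
   0.30075419,
   0.34712807,
   0.2078315,
   -0.04499622,
   -0.29237795,
   -0.45720414,
   -0.53150011,
   -0.54520572,
   -0.53073656,
   -0.51248578
  ],
  [
   -0.43496721,
   -0.42767788,
   -0.41212544,
   -0.38772187,
   -0.34849318,
   -0.28323919,
   -0.20110787,
   -0.14280282,
   -0.15313908,
   -0.23519679,
   -0.35185434,
   -0.46077586,
   -0.53542937,
   -0.57067439,
   -0.57526416,
   -0.56197164,
   -0.54573299
  ],
  [
   -0.46168624,
   -0.45310207,
   -0.43587902,
   -0.41216063,
   -0.38342598,
   -0.34731537,
   -0.31183634,
   -0.30185549,
   -0.33625579,
   -0.39785944,
   -0.45997952,
   -0.51363096,
   -0.55523734,
   -0.5809883,
   -0.58990434,
   -0.58477774,
   -0.57452565
  ],
  [
   -0.4787623,
   -0.47049678,
   -0.45325445,
   -0.42782026,
   -0.39677811,
   -0.36185839,
   -0.33283328,
   -0.33428566,
   -0.37986095,
   -0.43949934,
   -0.48433078,
   -0.51846096,
   -0.54939082,
   -0.57525381,
   -0.59181256,
   -0.59699483,
   -0.59476869
  ],
  [
   -0.48758043,
   -0.47929681,
   -0.46213628,
   -0.43526873,
   -0.39974101,
   -0.35892093,
   -0.32519878,
   -0.32762943,
   -0.38114715,
   -0.44608075,
   -0.48739892,
   -0.51435862,
   -0.54073975,
   -0.56700693,
   -0.58857424,
   -0.60128931,
   -0.60551493
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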