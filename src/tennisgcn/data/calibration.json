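{
 "noise_sd": 0.3,
 "class_separation": 0.8,
 "calibrated_by": "scripts/calibrate.py",
 "rule": "hardest grid point with fuzzy per-fraction mean >= 0.822, raw >= 0.745, and nonnegative mean fuzzy-raw paired difference (fractions 45/55/65%, 2 replicates)",
 "grid_results": [
  {
   "class_separation": 0.6,
   "noise_sd": 0.45,
   "fuzzy_min": 0.668724279835391,
   "raw_min": 0.7693602693602694,
   "diff_mean": -0.09554094739279928,
   "fuzzy_means": [
    0.7391,
    0.6687,
    0.7646
   ],
   "raw_means": [
    0.7694,
    0.8086,
    0.881
   ]
  },
  {
   "class_separation": 0.65,
   "noise_sd": 0.45,
   "fuzzy_min": 0.7160493827160493,
   "raw_min": 0.6903292181069959,
   "diff_mean": -0.05271408975112679,
   "fuzzy_means": [
    0.7466,
    0.716,
    0.7976
   ],
   "raw_means": [
    0.8485,
    0.6903,
    0.8796
   ]
  },
  {
   "class_separation": 0.65,
   "noise_sd": 0.4,
   "fuzzy_min": 0.7843915343915344,
   "raw_min": 0.7736625514403292,
   "diff_mean": -0.02891792706607521,
   "fuzzy_means": [
    0.8476,
    0.821,
    0.7844
   ],
   "raw_means": [
    0.8838,
    0.7737,
    0.8823
   ]
  },
  {
   "class_separation": 0.7,
   "noise_sd": 0.4,
   "fuzzy_min": 0.8333333333333333,
   "raw_min": 0.8353909465020576,
   "diff_mean": -0.019778917927066098,
   "fuzzy_means": [
    0.8746,
    0.8549,
    0.8333
   ],
   "raw_means": [
    0.8847,
    0.8354,
    0.9021
   ]
  },
  {
   "class_separation": 0.75,
   "noise_sd": 0.35,
   "fuzzy_min": 0.8737373737373737,
   "raw_min": 0.8919753086419753,
   "diff_mean": -0.007802896691785577,
   "fuzzy_means": [
    0.8737,
    0.8889,
    0.922
   ],
   "raw_means": [
    0.9007,
    0.892,
    0.9153
   ]
  },
  {
   "class_separation": 0.8,
   "noise_sd": 0.3,
   "fuzzy_min": 0.9063786008230452,
   "raw_min": 0.8940329218106996,
   "diff_mean": 0.0072818128373683955,
   "fuzzy_means": [
    0.9184,
    0.9064,
    0.9339
   ],
   "raw_means": [
    0.9234,
    0.894,
    0.9193
   ]
  }
 ]
}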