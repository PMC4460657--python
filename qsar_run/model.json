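{
 "coef_se": {
  "E_54": 0.00392386431761467,
  "S_138": 3.759225035593762
 },
 "coefficients": {
  "E_54": -0.06897216507734266,
  "S_138": 9.710419724342609
 },
 "intercept": 5.6512047019090765,
 "intercept_se": 0.21873584850661204,
 "n_train": 9,
 "provenance": {
  "grid_hash": "e5dfe2e918160b32",
  "split_hash": "b0d65fb6ad489287"
 },
 "selected": [
  "E_54",
  "S_138"
 ],
 "stats": {
  "f_stat": 161.3913517485033,
  "pred_r2": 0.8551612094553251,
  "pred_r2_se": 0.5734940117048968,
  "q2": 0.9570397386858777,
  "q2_se": 0.3332558258378329,
  "r2": 0.9817508648229282,
  "r2_se": 0.2172028088371905
 },
 "training_mean_y": 5.1953216666666675,
 "training_ranges": {
  "E_54": [
   -30.0,
   30.0
  ],
  "S_138": [
   -0.09406656141514941,
   -0.03265613522060014
  ]
 },
 "training_sd": {
  "E_54": 19.661202360332865,
  "S_138": 0.020522285751091263
 }
}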