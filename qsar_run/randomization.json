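{
 "actual": {
  "pred_r2": 0.8551612094553251,
  "q2": 0.9570397386858777,
  "r2": 0.9817508648229282
 },
 "areas_percent": {
  "pred_r2": 67.27511189005465,
  "q2": 88.32713443708066,
  "r2": 98.61827868725767
 },
 "n_permutations": 5,
 "p_values": {
  "pred_r2": 0.16666666666666666,
  "q2": 0.16666666666666666,
  "r2": 0.16666666666666666
 },
 "permuted": {
  "pred_r2": [
   -9480.901775912747,
   -0.366609666973688,
   0.34721893081380606,
   0.34618285476329413,
   -2.147090356973192
  ],
  "q2": [
   0.7012810243544607,
   0.9017993640692643,
   0.6595850605733814,
   0.26658398634892055,
   0.8075262916185753
  ],
  "r2": [
   0.8490725593456286,
   0.9521590502002178,
   0.8795566745839645,
   0.8825483438210886,
   0.9141405101929744
  ]
 },
 "seed": 5,
 "z_scores": {
  "pred_r2": 0.4475226161306537,
  "q2": 1.191500115672067,
  "r2": 2.202437403167532
 }
}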