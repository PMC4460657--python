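{
 "config_hash": "ba82c05d97025ab6",
 "seed": 5,
 "stages": {
  "align": {
   "max_rmsd": 1.3469788465682918e-15,
   "n_molecules": 12,
   "seconds": 0.006
  },
  "fields": {
   "descriptors_after": 857,
   "descriptors_before": 882,
   "grid_hash": "e5dfe2e918160b32",
   "grid_points": 441,
   "seconds": 0.02
  },
  "screen": {
   "n_hits": 0,
   "n_library": 20,
   "seconds": 0.022
  },
  "split": {
   "n_test": 3,
   "n_train": 9,
   "radius": 24.0,
   "seconds": 0.002
  },
  "train": {
   "pred_r2": 0.8551612094553251,
   "q2": 0.9570397386858777,
   "r2": 0.9817508648229282,
   "seconds": 0.07,
   "selected": [
    "E_54",
    "S_138"
   ]
  },
  "validate": {
   "seconds": 0.44,
   "z_scores": {
    "pred_r2": 0.4475226161306537,
    "q2": 1.191500115672067,
    "r2": 2.202437403167532
   }
  }
 }
}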