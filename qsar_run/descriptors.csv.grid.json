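{
 "grid_hash": "e5dfe2e918160b32",
 "grid": {
  "origin": [
   -8.202500000000002,
   -5.7509000000000015,
   -6.1073
  ],
  "spacing": 2.0,
  "counts": [
   9,
   7,
   7
  ]
 }
}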