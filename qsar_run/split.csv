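compound_id,set
cmpd_002,train
cmpd_012,train
cmpd_004,train
cmpd_010,train
cmpd_011,train
cmpd_003,train
cmpd_006,train
cmpd_005,train
cmpd_008,train
cmpd_001,test
cmpd_009,test
cmpd_007,test
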