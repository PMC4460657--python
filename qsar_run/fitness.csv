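compound_id,set,observed,predicted
cmpd_002,train,6.951705,7.129302169831839
cmpd_012,train,6.774947,6.699108961901751
cmpd_004,train,5.816341,5.852578496533238
cmpd_010,train,5.770736,5.804944352571251
cmpd_011,train,5.268937,5.231960665228741
cmpd_003,train,5.231139,5.167306968727603
cmpd_006,train,4.798687,4.444937541999663
cmpd_005,train,3.212491,3.1628208731839287
cmpd_008,train,2.932912,3.2649349700218817
cmpd_001,test,6.390851,6.01187420294268
cmpd_009,test,4.956957,5.823522268675504
cmpd_007,test,2.887466,3.190990903099657
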