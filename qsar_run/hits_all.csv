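rank,compound_id,predicted_pIC50,extrapolation
1,cmpd_011,7.4413,0.0637
2,cmpd_004,7.3266,0.0000
3,cmpd_003,7.2968,0.0000
4,cmpd_013,6.8694,0.0000
5,cmpd_017,6.6070,0.0401
6,cmpd_002,6.4580,0.0000
7,cmpd_020,6.2689,0.0000
8,cmpd_018,5.9190,0.0601
9,cmpd_007,5.8963,0.0000
10,cmpd_005,5.6042,0.0000
11,cmpd_016,5.3715,0.0000
12,cmpd_019,5.1389,0.0000
13,cmpd_008,4.7457,0.0000
14,cmpd_010,4.6142,0.0000
15,cmpd_009,4.5691,0.0000
16,cmpd_014,4.3667,0.0000
17,cmpd_015,4.2238,0.0000
18,cmpd_012,3.2139,0.0000
19,cmpd_001,2.9734,-1.2000
20,cmpd_006,2.5799,-0.1487
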