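subject,test_id,fm3,fm3a,fm7,fm_ca
S1,T1,1,1,1-,0.490
S1,T2,1,1,1-,0.396
S1,T3,1,1,1,0.511
S2,T1,1,1,1-,0.390
S2,T2,1,1,1+,0.585
S2,T3,1,1,1-,0.437
S3,T1,2,2,2,0.864
S3,T2,2,2,2-,0.849
S3,T3,2,1,2,0.564
S4,T1,1,1,1+,0.543
S4,T2,2,2,2,0.978
S4,T3,2,2,2,0.888
S5,T1,2,2,2,0.791
S5,T2,1,1,1,0.484
S5,T3,2,2,2-,0.846
S6,T1,2,2,2-,0.623
S6,T2,1,1,1-,0.367
S6,T3,2,2,2,0.970
S7,T1,1,1,1-,0.360
S7,T2,1,1,1-,0.381
S7,T3,1,1,1,0.523
S8,T1,0,0,0,0.061
S8,T2,1,1,1-,0.364
S8,T3,0,0,0,0.008
S9,T1,0,0,0,0.245
S9,T2,0,0,0,0.259
S9,T3,0,0,0+,0.319
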