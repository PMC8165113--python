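patient_id,sex,age,bmi,cabg,diabetes,ckd,smoking
M001,M,78.403700000000001,26.221399999999999,0,1,0,former
M002,M,72.709900000000005,20.272200000000002,1,0,0,never
M003,M,76.262600000000006,28.971800000000002,1,0,0,never
M004,M,72.129199999999997,26.679300000000001,1,0,1,former
M005,M,78.814700000000002,25.853899999999999,1,0,1,former
M006,M,75.880099999999999,30.2149,1,1,0,never
M007,M,74.6083,31.7302,1,0,0,never
M008,M,69.990200000000002,35.232900000000001,0,1,1,former
M009,M,73.316199999999995,31.1266,1,1,0,never
M010,M,77.840599999999995,22.514399999999998,0,0,0,former
M011,M,79.193100000000001,27.7226,1,0,0,never
M012,M,70.749399999999994,30.875900000000001,0,0,1,former
F001,F,72.706999999999994,27.601700000000001,0,0,0,former
F002,F,72.072000000000003,26.752199999999998,1,1,1,never
F003,F,76.380300000000005,26.813800000000001,0,0,0,never
F004,F,74.706999999999994,29.7941,0,0,0,former
F005,F,75.414100000000005,16.612300000000001,0,1,0,never
F006,F,80.781300000000002,29.3992,0,1,0,never
F007,F,63.617800000000003,26.2226,1,0,0,former
F008,F,76.111599999999996,23.348400000000002,0,0,0,former
F009,F,81.045400000000001,33.0351,0,0,1,never
F010,F,75.855599999999995,35.946899999999999,1,0,1,never
F011,F,68.5244,24.824000000000002,1,0,0,former
F012,F,68.427000000000007,17.736599999999999,0,0,0,former
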