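age_lo_months,age_hi_months,boys_obs,girls_obs
60,72,5190,4972
72,84,577,574
84,96,4641,4466
96,120,2388,2049
120,132,979,984
132,144,3973,3846
144,156,3033,2735
156,168,1178,1267
168,180,4259,4040
180,192,2811,2540
192,204,1079,1147
204,216,1857,1915
216,264,1430,1430
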