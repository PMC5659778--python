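parity_class,dp_category,ady,a,b,c,k,fat_pct,protein_pct,lactose_pct
1,heifer,23.9,31.6,-0.0447,-16.1,0.06,4.48,3.55,4.62
2,std56,28.9,40.6,-0.0708,-16.1,0.06,4.50,3.59,4.53
2,short28,25.9,37.6,-0.0708,-16.1,0.06,4.64,3.75,4.55
2,no0_after56,22.1,33.8,-0.0708,-16.1,0.06,4.81,3.93,4.51
gt2,std56,30.5,44.1,-0.0835,-16.1,0.06,4.51,3.51,4.48
gt2,short28,27.7,41.3,-0.0835,-16.1,0.06,4.49,3.62,4.48
gt2,no0_after56,24.4,38.0,-0.0835,-16.1,0.06,4.60,3.71,4.41
gt2,no0_after0,27.0,40.6,-0.0835,-16.1,0.06,4.53,3.62,4.41
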