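parity_class,dp_length,median,p5,p95,n,p_fertility_culling
1,56,374,327,477,2348,0.080
2,56,381,330,487,1116,0.075
2,28,365,325,482,495,0.052
2,0,359,316,464,342,0.039
gt2,56,385,333,489,1850,0.078
gt2,28,378,328,480,629,0.074
gt2,0,370,321,473,573,0.037
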