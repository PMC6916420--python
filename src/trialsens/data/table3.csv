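row,n,pct_missing,dead_c,missing_c,dead_t,missing_t,odds_ratio,reject_r2,reject_r5
a,100,5.5,35,6,18,5,0.39,Y,Y
b,1000,5.3,302,54,247,53,0.75,Y,Y
c,10000,5.2,3007,495,2812,551,0.92,N,N
d,100,10.0,38,11,21,9,0.40,Y,Y
e,1000,10.4,301,105,247,103,0.75,Y,N
f,10000,10.2,2787,1017,2611,1030,0.91,N,N
g,100,15.0,34,18,19,12,0.39,Y,Y
h,1000,15.0,258,155,209,146,0.74,N,N
i,10000,15.0,2592,1518,2438,1475,0.91,N,N
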