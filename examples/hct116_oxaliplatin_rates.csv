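concentration,rate_mean,rate_se
0,0.30,0.04
0.1,0.30,0.04
0.2,0.27,0.03
0.4,0.25,0.03
0.8,0.20,0.03
1.6,0.14,0.04
3.13,0.08,0.03
6.25,-0.01,0.04
12.5,-0.05,0.04
25,-0.21,0.06
50,-0.44,0.04
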