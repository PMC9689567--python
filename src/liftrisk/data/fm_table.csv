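freq_per_min,short_v_lt75,short_v_ge75,medium_v_lt75,medium_v_ge75,long_v_lt75,long_v_ge75
0.2,1.00,1.00,0.95,0.95,0.85,0.85
0.5,0.97,0.97,0.92,0.92,0.81,0.81
1,0.94,0.94,0.88,0.88,0.75,0.75
2,0.91,0.91,0.84,0.84,0.65,0.65
3,0.88,0.88,0.79,0.79,0.55,0.55
4,0.84,0.84,0.72,0.72,0.45,0.45
5,0.80,0.80,0.60,0.60,0.35,0.35
6,0.75,0.75,0.50,0.50,0.27,0.27
7,0.70,0.70,0.42,0.42,0.22,0.22
8,0.60,0.60,0.35,0.35,0.18,0.18
9,0.52,0.52,0.30,0.30,0.00,0.15
10,0.45,0.45,0.26,0.26,0.00,0.13
11,0.41,0.41,0.00,0.23,0.00,0.00
12,0.37,0.37,0.00,0.21,0.00,0.00
13,0.00,0.34,0.00,0.00,0.00,0.00
14,0.00,0.31,0.00,0.00,0.00,0.00
15,0.00,0.28,0.00,0.00,0.00,0.00
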