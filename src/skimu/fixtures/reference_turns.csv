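trial,turn,side,duration_s,max_pressure_ratio
1,1,R,2.32,0.89
1,2,L,2.05,0.81
1,3,R,2.07,0.85
1,4,L,1.62,0.92
1,5,R,2.69,0.85
1,6,L,3.10,0.97
2,1,R,2.25,0.94
2,2,L,1.82,0.88
2,3,R,1.71,0.88
2,4,L,1.57,0.83
2,5,R,1.86,0.78
2,6,L,1.50,0.89
3,1,R,2.49,0.80
3,2,L,1.80,0.88
3,3,R,2.02,0.72
3,4,L,1.62,0.83
3,5,R,1.94,0.72
3,6,L,1.55,0.87
4,1,R,2.62,0.93
4,2,L,1.72,0.87
4,3,R,1.79,0.78
4,4,L,1.57,0.87
4,5,R,2.14,0.77
4,6,L,1.39,0.89
5,1,R,2.34,0.93
5,2,L,1.61,0.81
5,3,R,1.81,0.77
5,4,L,1.52,0.76
5,5,R,1.74,0.76
5,6,L,1.46,0.87
6,1,R,2.30,0.92
6,2,L,1.85,0.76
6,3,R,1.80,0.83
6,4,L,1.39,0.85
6,5,R,2.05,0.70
6,6,L,1.74,0.84
7,1,R,2.28,0.83
7,2,L,1.80,0.87
7,3,R,1.85,0.82
7,4,L,1.51,0.88
7,5,R,1.74,0.67
7,6,L,1.53,0.88
8,1,R,2.39,0.89
8,2,L,1.77,0.86
8,3,R,1.97,0.69
8,4,L,1.42,0.89
8,5,R,1.75,0.66
8,6,L,1.50,0.90
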