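0.2
0.2 0.2
1 4 5
254 36 98 11
0.2 154 262 0.2 0.2
0.2 0.2 183 862 0.2 262
2 0.2 121 12 81 3 44
0.2 41 18 0.2 12 314 15 0.2
26 2 21 7 63 11 7 3 0.2
4 2 13 1 79 16 2 1 6 515
0.2 209 467 2 0.2 349 106 0.2 0.2 3 4
121 5 79 0.2 312 67 0.2 56 0.2 515 885 106
13 5 2 0.2 184 0.2 0.2 1 14 118 263 11 322
49 0.2 17 0.2 0.2 39 8 0.2 1 0.2 12 17 5 15
673 3 398 44 664 52 31 226 11 7 8 144 112 36 87
244 0.2 166 0.2 183 44 43 0.2 19 204 48 7 289 14 47 66
0.2 0.2 8 0.2 22 7 11 2 0.2 0.2 21 16 71 54 0.2 2 0.2
1 4 251 0.2 72 87 8 9 191 12 2 117 71 792 18 3 46 38
34 0.2 23 0.2 35 0.2 14 3 0.2 1855 85 26 281 52 32 61 544 0.2 2

0.054116 0.018227 0.039903 0.02016 0.009709 0.018781 0.024289 0.068183 0.024518 0.092638 0.148658 0.021718 0.061453 0.088668 0.041826 0.09103 0.049194 0.029786 0.039443 0.0577
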