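27
98 32
12 0 905
36 23 0 0
89 246 103 134 0
198 1 148 1153 0 716
24 9 139 125 11 28 81
23 24 535 86 28 606 43 1
65 64 77 24 44 18 61 0 7
41 15 34 0 0 73 11 7 44 257
26 464 318 71 0 153 83 27 26 46 18
72 9 1 0 0 114 3 17 0 336 527 243
18 14 14 0 0 0 0 15 48 196 157 0 92
25 103 42 13 19 153 51 34 94 12 32 33 17 11
409 154 495 95 161 56 79 234 35 24 17 96 62 46 245
371 26 229 66 16 53 34 3 22 192 33 136 104 13 78 55
0 201 23 0 0 0 0 0 27 0 46 0 0 76 0 75 0
24 8 95 0 96 0 22 0 127 37 28 13 0 698 0 34 42 61
208 24 15 18 49 35 37 54 44 889 175 1 258 12 48 3 157 0 28

0.087127 0.040904 0.040432 0.046872 0.033474 0.038255 0.04953 0.088612 0.033618 0.036886 0.085357 0.080482 0.014753 0.039772 0.05068 0.069577 0.058542 0.010494 0.029916 0.064718
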