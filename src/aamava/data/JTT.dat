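58
54 45
81 16 528
56 113 34 1
57 31 86 49 9
105 29 58 767 5 323
179 137 81 13 59 26 119
27 328 391 112 69 597 26 23
36 22 47 11 17 9 12 6 16
3 38 12 7 23 72 9 6 56 229
35 646 263 26 7 292 181 27 45 21 14
54 44 3 15 31 43 18 14 33 479 388 65
15 5 1 4 78 4 5 5 4 89 248 4 43
194 74 15 15 14 164 18 24 115 1 102 21 16 17
378 101 503 59 223 53 3 201 73 4 59 47 29 92 285
475 64 232 38 42 51 32 33 46 245 25 103 226 12 118 477
9 126 8 4 115 18 1 55 8 9 52 1 24 53 6 35 12
11 2 7 46 209 24 7 8 573 32 24 8 18 536 1 63 21 71
298 17 16 31 62 2 45 47 11 961 18 14 323 62 23 38 112 25 16

0.076748 0.051691 0.042645 0.051544 0.019803 0.040752 0.06183 0.073152 0.022944 0.053761 0.091904 0.058676 0.023826 0.040126 0.050901 0.068765 0.058565 0.014261 0.032102 0.066005
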