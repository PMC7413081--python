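34
51 35
1 3 384
439 92 128 1
32 221 236 78 7
81 1 79 542 1 372
135 41 94 61 48 18 7
3 9 32 91 124 387 34 68
1 24 35 1 104 33 1 1 34
45 18 15 5 11 54 21 3 51 385
38 593 123 2 16 309 141 3 76 34 23
235 57 1 1 156 158 1 37 116 375 581 134
1 7 49 1 7 1 1 7 141 64 179 14 247
97 24 33 55 1 68 52 17 44 1 22 43 1 11
46 102 294 136 75 225 95 152 183 4 24 77 1 2 134
258 64 148 55 117 146 82 7 49 72 25 11 131 69 62 671
5 13 16 1 55 1 17 23 48 39 47 6 111 182 9 14 1
55 47 28 1 131 45 1 21 307 26 64 1 74 1017 14 31 34 176
197 29 21 6 295 36 35 3 1 1048 112 19 236 92 25 39 196 26 59

0.0646 0.0453 0.0376 0.0422 0.0114 0.0606 0.0607 0.0639 0.0273 0.0679 0.1018 0.0751 0.015 0.0287 0.0681 0.0488 0.0622 0.0251 0.0318 0.0619
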