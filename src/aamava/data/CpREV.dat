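105
227 357
175 43 4435
669 823 538 1
157 1745 768 4 1
499 152 1055 3691 1 3122
665 243 653 431 303 133 379
66 715 1405 331 441 1269 162 19
145 136 168 1 28 92 148 4 29
197 203 113 1 396 286 82 2 66 1745
236 4482 243 412 48 3313 2629 263 305 345 218
185 125 61 47 159 202 113 21 1 1772 1351 193
68 53 97 22 726 1 145 25 127 454 1268 72 327
49 87 173 17 285 323 185 28 152 117 219 302 1 43
244 385 2085 59 2331 396 568 691 303 216 516 868 93 487 1202
134 314 1393 266 576 241 369 92 32 104 156 918 645 148 26 2151
14 23 4 18 435 53 63 82 69 42 159 1 86 468 49 73 29
56 323 754 281 1466 391 142 1 1971 89 189 247 215 237 97 522 71 346
968 92 83 75 592 54 2 91 25 4797 865 249 475 317 122 167 76 1 119

0.0755 0.0621 0.041 0.0371 0.0091 0.0382 0.0495 0.0838 0.0246 0.0806 0.1011 0.0504 0.022 0.0506 0.0431 0.0622 0.0543 0.0181 0.0307 0.066
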