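23.18
26.95 13.24
17.67 1.9 794.38
59.93 103.33 58.94 1.9
1.9 220.99 173.56 55.28 75.24
9.77 1.9 63.05 583.55 1.9 313.56
120.71 23.03 53.3 56.77 30.71 6.75 28.28
13.9 165.23 496.13 113.99 141.49 582.4 49.12 1.9
96.49 1.9 27.1 4.34 62.73 8.34 3.31 5.98 12.26
25.46 15.58 15.16 1.9 25.65 39.7 1.9 2.41 11.49 329.09
8.36 141.4 608.7 2.31 1.9 465.58 313.86 22.73 127.67 19.57 14.88
141.88 1.9 65.41 1.9 6.18 47.37 1.9 1.9 11.97 517.98 537.53 91.37
6.37 4.69 15.2 4.98 70.8 19.11 2.67 1.9 48.16 84.67 216.06 6.44 90.82
54.31 23.64 73.31 13.43 31.26 137.29 12.83 1.9 60.97 20.63 40.1 50.1 18.84 17.31
387.86 6.04 494.39 69.02 277.05 54.11 54.71 125.93 77.46 47.7 73.61 105.79 111.16 64.29 169.9
480.72 2.08 238.46 28.01 179.97 94.93 14.82 11.17 44.78 368.43 126.4 136.33 528.17 33.85 128.22 597.21
1.9 21.95 10.68 19.86 33.6 1.9 1.9 10.92 7.08 1.9 32.44 24 21.71 7.84 4.21 38.58 9.99
6.48 1.9 191.36 21.21 254.77 38.82 13.12 3.21 670.14 25.01 44.15 51.17 39.96 465.58 16.21 64.92 38.73 26.25
195.06 7.64 1.9 1.9 1.9 19 21.14 2.53 1.9 1222.94 91.67 1.9 387.54 6.35 8.23 1.9 204.54 5.37 1.9

0.072 0.019 0.039 0.019 0.006 0.025 0.024 0.056 0.028 0.088 0.169 0.023 0.054 0.061 0.054 0.072 0.086 0.029 0.033 0.043
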