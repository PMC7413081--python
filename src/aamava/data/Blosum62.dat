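0.7357903897
0.4853910555 1.297446705
0.5431618209 0.5009644086 3.180100048
1.45999531 0.2278265742 0.3973589499 0.2408366148
1.199705705 3.02083361 1.839216147 1.190945703 0.3298015046
1.170949043 1.36057419 1.240488509 3.761625208 0.1407488918 5.528919178
1.955883575 0.4187633085 1.355872344 0.798473249 0.4182031923 0.6098463054 0.4235799922
0.716241445 1.456141166 2.414501434 0.778142664 0.3540581098 2.435341131 1.626891057 0.539859125
0.6058990037 0.2320364451 0.2830173263 0.4185557325 0.7748940228 0.2362024512 0.1868480469 0.1892962924 0.2527184479
0.8000165305 0.6227116697 0.2118881596 0.2181315776 0.8318426401 0.5807370932 0.3726251751 0.2177211592 0.3480722098 3.890963773
1.295201267 5.411115141 1.593137043 1.032447925 0.2850788009 3.945277675 2.802427152 0.7520424403 1.022507036 0.4061935866 0.4455702743
1.253758267 0.9836929875 0.6484412788 0.222621898 0.7676888235 2.494896077 0.5554153975 0.4594361736 0.9843115254 3.364797763 6.03055938 1.073061184
0.4929646797 0.3716446932 0.3548612492 0.2817306942 0.4413374712 0.1443569598 0.2914090842 0.3681664645 0.7145337039 1.517359326 2.064839703 0.2669247505 1.773855169
1.173275901 0.4481336617 0.4948870437 0.730628273 0.3560084988 0.8585705757 0.9265639348 0.5040865995 0.5270073392 0.3883554092 0.3745556875 1.047383451 0.4541236251 0.2335979096
4.325092687 1.122783104 2.904101656 1.582754142 1.197188415 1.934870925 1.769893239 1.509326253 1.117029763 0.3575444125 0.3529691845 1.752165918 0.9187234157 0.5400276448 1.169129578
1.729178019 0.9146659546 1.898173635 0.9341875094 1.119831359 1.277480295 1.071097236 0.6414360114 0.5854070902 1.179091197 0.9152598577 1.303875201 1.488548054 0.4882061188 1.005451683 5.151556292
0.4658393677 0.4263823101 0.1914820462 0.1453450463 0.5276644189 0.7586538086 0.4076356489 0.5083589246 0.3012486008 0.3419857875 0.6914746346 0.3322430406 0.8881010982 2.074324893 0.25221483 0.3879256221 0.5131281269
0.7182066976 0.7205174412 0.538222519 0.261422209 0.4702377337 0.9589897429 0.5967193003 0.308055737 4.218953969 0.6746170932 0.8112458563 0.7179934869 0.9516821622 6.747260431 0.3694053194 0.7967515208 0.8010102432 4.054419007
2.187774522 0.4383883438 0.312858798 0.2581292894 1.116352479 0.5307857901 0.5242538463 0.2533407902 0.2015559718 8.311839405 2.231405689 0.4981384753 2.575850755 0.8381196102 0.4969084107 0.5619254574 2.253074051 0.2665087314 1

0.074 0.052 0.045 0.054 0.025 0.034 0.054 0.074 0.026 0.068 0.099 0.058 0.025 0.047 0.039 0.057 0.051 0.013 0.032 0.073
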