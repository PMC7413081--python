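0.1386587648
0.05336657871 0.161000889
0.5848523056 0.006771842532 7.737392871
0.02644709512 0.1672070082 1.302498568e-05 0.01413206255
0.3537539816 3.292716942 0.5306426553 0.1454693884 0.00254733398
1.484234503 0.1248976169 0.06165219219 5.370511279 3.911069927e-11 1.195629122
1.132313122 1.190624465 0.3225246479 1.934832784 0.1169414591 0.1080513412 1.593098825
0.2147578622 1.879569938 1.387096032 0.8875705494 0.0218446167 5.330313412 0.2564918634 0.05877452743
0.1499267342 0.2461171718 0.2185719754 0.0140859175 0.001112158073 0.0288399503 0.01421071187 1.626622831e-05 0.243190142
0.02311695153 0.2960455575 0.0008358731745 0.005730682085 0.005613627249 1.020366955 0.01649953554 0.006516229377 0.3216116936 3.512072282
0.4743336102 15.30009662 2.646847965 0.2900429801 3.83228119e-06 2.559587177 3.881488809 0.2641489293 0.3473027912 0.2277079972 0.1292236392
0.05874542315 0.8901623456 0.005251687789 0.04176296373 0.1114573103 0.1902591813 0.3139743514 0.001500466923 0.001273508905 9.017954203 6.746936485 1.331291619
0.08049090943 0.01605503148 0.0008364456156 1.060010285e-06 0.1040536662 0.03268065701 0.001003500825 0.001236644954 0.1190285062 1.463357278 2.986800036 0.3198959045 0.279910509
0.6593114779 0.1540271799 0.03644177191 0.1885394564 1.593120602e-13 0.7127695991 0.3195588284 0.03863176146 0.9244669142 0.08054332682 0.6343085209 0.1957506318 0.05686932165 0.007132430466
3.011344519 0.9501384101 3.881310531 0.3383721834 0.3362633445 0.4878224985 0.307140298 1.585646577 0.5807042498 0.2903810753 0.5707666932 0.2838076716 0.007026588287 0.9966856696 2.087385344
5.418298175 0.183076905 2.140332316 0.1354812326 0.01197526578 0.6023409634 0.2801248951 0.01880802995 0.3687135734 2.904052286 0.04492635668 1.5269642 2.031511321 0.0001349062395 0.542251094 2.206859934
0.195966354 1.369429408 0.00053628404 1.489387372e-05 0.0941066801 0.04402052008 0.1552454921 0.1964864471 0.02237291911 0.03213214996 0.4312776629 4.976414455e-05 0.07046003852 0.8147530938 0.0004310207023 0.0998357527 0.2070662055
0.01828928822 0.09985549725 0.3731019265 0.5253985429 0.6016924311 0.07220593541 0.1040928703 0.0748149971 6.448954446 0.2739342632 0.3400584684 0.01241622155 0.8742721745 5.393924245 0.0001822948815 0.3925522399 0.1248980204 0.4277554304
3.53200527 0.1039643864 0.01025751725 0.2971239752 0.05490456395 0.406697814 0.2850479483 0.3372296189 0.09863135467 14.39405219 0.8905985794 0.07312792964 4.904842235 0.5925879855 0.05897197515 0.0882564233 0.6541091083 0.2569004614 0.1675816468

0.0470718 0.0509102 0.0742143 0.0478596 0.0250216 0.0333036 0.0545874 0.0763734 0.0199642 0.0671336 0.0714981 0.0567845 0.0181507 0.0304961 0.0506561 0.0884091 0.0743386 0.0185237 0.0314741 0.0632292
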