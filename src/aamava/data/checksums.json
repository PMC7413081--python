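{
 "Blosum62.dat": "13508ff1eb43328871ecfbc66904210b580e32d8ebddcd505321cc52cc410a38",
 "CpREV.dat": "3c8450947330c79d957be95ab7fd2329884defe54d3a4388c0f4321ea189caf1",
 "DCMut.dat": "4395e2d455a2f7d0a691106d1976113eb3662028cb3bc460815335ef97ef3d93",
 "Dayhoff.dat": "fbe9532d22aceb8ea93098b16b977b61b16014b37cee7b3f4676a6bf01bd8325",
 "FLU.dat": "3047c2dcfc40321f87e1deff0ff10bb5ac64a6adb8f542a01c2d30eebe9e509f",
 "HIVb.dat": "55a9f76e8aa4fc7d05be64722a5a059b7349efdb62574a59dfe50c3de6bf842e",
 "HIVw.dat": "a06406156014adb7ecd7c32451cfd0397fd0c0b9bdddb04afa2040c4be375950",
 "JTT.dat": "e1521f30a3fe331be425b8a70dfa41093372799729e25d414a983eb532039b2d",
 "LG.dat": "dd4ea77af54049d3f54432949fe524f376f4044f77e4bd4ddbcf7164326d7e89",
 "MtArt.dat": "4c8c9ddf6d42db17cb0e69e15e01c6f431593a093193046ac5e2e0b517654fe7",
 "MtMam.dat": "1d9348f20748a834f2a0e4734dba248b2662869c206205251c589726441d075b",
 "RtREV.dat": "7370320576d4aea3c8b557e40aea02ccee06d92a2c6ea141efa5c765a7b03b5e",
 "VT.dat": "6a591787cdb215dba1e03c3e5a69b6665a3a26c30a5af7619ec216e915f113aa",
 "WAG.dat": "0204276325bef43abb21b855820a58c7d4402bff470cfaef308c8899a9890e5e",
 "mtREV.dat": "70141bb69d427a07c79663c813f1c19285109a804f7a653f10a9d638dfe5fdf8"
}
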