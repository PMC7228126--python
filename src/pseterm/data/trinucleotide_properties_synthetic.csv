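property,AAA,AAC,AAG,AAT,ACA,ACC,ACG,ACT,AGA,AGC,AGG,AGT,ATA,ATC,ATG,ATT,CAA,CAC,CAG,CAT,CCA,CCC,CCG,CCT,CGA,CGC,CGG,CGT,CTA,CTC,CTG,CTT,GAA,GAC,GAG,GAT,GCA,GCC,GCG,GCT,GGA,GGC,GGG,GGT,GTA,GTC,GTG,GTT,TAA,TAC,TAG,TAT,TCA,TCC,TCG,TCT,TGA,TGC,TGG,TGT,TTA,TTC,TTG,TTT
Dnase I,-1.8687,0.5246,-1.6379,-1.2552,-0.7380,0.2667,-0.1004,1.2989,-0.0236,0.9996,1.6636,-1.1604,-1.0829,1.4270,-0.3349,-1.5083,0.2807,-0.5495,0.5751,-2.2795,0.2044,-0.0960,0.4710,-0.4064,0.9756,-0.7791,1.0381,-0.3419,-1.4533,0.8231,0.7019,-0.2702,-0.5190,-0.0065,-0.5581,0.5817,0.8972,-0.1532,1.4419,1.1698,0.0925,0.4260,1.2298,1.9597,-0.2258,0.3584,0.3610,-0.6682,-0.8397,-0.3433,-0.7965,-2.1413,0.4567,2.3802,-0.5238,0.1573,-1.2159,1.2488,1.3277,-0.1403,-0.9040,0.5816,-0.1042,-0.8946
Bendability (DNAse),-0.8248,-1.3171,-2.0440,2.4070,0.4696,0.2521,1.4611,1.3440,0.8154,1.2636,-1.7131,0.3193,1.2806,0.8082,0.3828,0.7578,1.1740,-0.4623,1.0437,0.1387,0.6345,-1.5792,-0.9820,-0.2691,-1.8135,-0.7575,-0.5053,-1.2161,0.2645,-1.2040,0.2106,0.2039,0.8245,-1.2346,-0.3349,1.3318,0.9035,-0.4107,-1.5559,-0.0929,0.6488,0.0821,-0.4439,-0.5992,-0.1940,1.3832,0.5264,0.3961,0.7113,-1.1346,-0.3086,0.8103,0.3721,-1.5819,-1.5957,-0.7448,0.5775,-0.1281,-0.4561,1.0951,0.5242,0.5468,1.1191,-1.5801
Bendability (consensus),-0.5369,-0.1697,-1.1433,0.0339,1.0091,-0.1950,2.3169,-0.4763,-0.6574,1.0530,-0.4282,0.5765,-2.0356,1.5726,-0.3990,-0.6494,-0.2621,0.6446,-1.3015,-1.9766,-0.5555,-0.1800,-0.4955,0.0903,-1.9089,1.9745,0.3105,0.5274,-0.3937,1.0963,1.6546,-0.1167,-1.2928,0.5237,0.6135,-1.9831,1.5028,-1.1332,0.3394,0.3245,0.1190,-0.1608,1.4476,0.4991,0.4648,0.8625,0.6805,0.4431,-1.1539,-2.0099,-0.2044,-1.1566,1.1578,-0.0003,-0.5200,1.4992,-0.8013,1.1293,0.8757,-0.1697,0.1210,-0.5497,-0.2660,-0.1809
Trinucleotide GC Content,-0.0127,-0.9361,0.6997,-0.5325,1.1507,0.7938,-0.2164,1.3219,0.1335,-0.7833,-2.9860,-0.5463,-1.5927,0.1120,1.6157,0.6246,0.1863,0.1373,0.0228,-0.1960,-0.5652,-1.8414,2.1010,-0.6799,-1.4561,-0.4480,-0.7339,0.5405,-0.2189,0.9585,-0.7318,1.4704,-1.6469,-1.4153,-0.6390,0.4668,-0.0371,-1.2370,-1.2997,-2.1074,0.9792,0.0969,-1.0187,1.0653,1.5313,0.2064,1.1584,0.8571,0.1801,-0.4555,0.7227,0.5394,0.2278,0.4902,0.2608,-0.5327,1.5790,0.0873,0.3504,0.7410,-0.0175,0.4793,-0.3699,1.3660
Nucleosome positioning,0.1601,-0.8662,-0.6838,-0.5409,-1.0157,0.3784,0.1559,-0.8137,1.3667,1.2498,0.4673,-0.9188,-1.6664,-0.1264,-0.5366,-1.3417,1.0995,-0.5169,1.1380,-1.5701,0.2575,2.0407,-0.9331,0.3982,0.9031,1.3181,1.6796,0.7521,-1.6528,0.0131,1.6851,0.0556,-0.1474,1.5819,1.2898,-0.8830,-1.0265,0.8301,-0.6768,-0.2455,-0.8872,1.8026,1.3768,0.8573,-1.0503,-0.4827,0.9304,0.3609,0.0754,-1.2637,-0.1512,-1.5236,-1.2068,-0.5881,1.1849,-0.8956,0.0829,0.9003,0.0300,-0.3637,-1.8204,0.1459,0.5205,-0.6928
Consensus_roll,0.4634,0.2194,1.4983,1.2401,0.5406,-0.0193,-0.7774,1.3950,-0.6116,-0.0563,-0.2733,0.7867,0.2108,0.0499,0.4748,0.3733,1.3390,-0.2378,0.6026,1.2134,0.6907,-2.2361,-0.6297,0.0021,1.5057,1.3210,1.1709,0.1989,-0.8926,0.5973,-0.4609,-0.6139,1.2519,1.2379,-0.7746,0.2025,-0.4891,-2.8797,-0.5061,-1.7313,-0.3423,-0.2030,0.7456,-0.0482,0.0834,-0.2241,0.5686,-2.9897,0.9299,0.4742,-0.8527,1.2622,0.7894,-1.8291,-0.4594,-0.1787,-0.1351,-2.2354,-0.8085,0.1454,-0.1654,0.0571,0.0067,0.0126
Consensus_Rigid,-1.7764,-0.0845,0.4157,0.3178,0.6480,-0.8411,0.5318,-1.4371,-0.3224,1.1771,-0.6438,-0.9946,-1.4204,-1.2356,0.4123,-2.5842,-0.4317,0.9598,-0.4219,1.0901,1.4926,0.1856,1.3323,1.5699,1.7410,0.5173,0.5326,0.5527,-0.5103,-0.1800,-0.1879,-0.0417,1.4074,0.3419,-0.5420,0.7518,0.0092,1.2135,0.0220,0.5519,-0.1080,0.6632,-0.4467,0.7570,0.7798,-0.1793,-0.1907,0.9602,-3.1392,1.7925,0.4141,-0.3053,-0.4136,1.1221,0.2221,-0.3675,0.2561,0.0942,0.0556,-0.9545,-1.3230,-1.8598,-0.9027,-1.0453
Dnase I-Rigid,0.7951,0.4907,0.6138,-0.1288,1.1545,0.8593,0.4170,-1.4453,0.6215,-2.6541,-0.7442,0.5600,0.4822,0.0203,-0.6648,0.6601,0.8958,0.1011,-0.0368,-0.1089,-0.9839,-0.2216,-1.0557,0.0120,-1.5284,-0.6118,-1.4667,1.0149,0.2080,-0.0766,-0.1206,0.2868,1.3746,0.6138,-0.4184,-1.8584,1.6944,0.0760,-0.0068,1.3922,-0.3895,-3.0211,-1.4220,-1.0564,0.7644,0.4106,-1.2161,1.0636,0.9395,1.3599,-0.0528,0.1647,0.7041,-0.1082,-1.1164,-1.3104,-0.0084,0.7572,0.2589,0.7125,0.1022,0.7225,-0.7229,2.2517
MW-Daltons,-1.8928,-0.6325,0.1199,0.6624,-1.2300,0.5462,-2.2075,0.0881,-0.4884,0.4613,1.0077,-0.8471,-0.5053,-1.4994,-1.1102,-0.0655,-1.1064,-0.7057,-1.0568,0.6872,-0.7067,-0.1580,0.9684,0.4604,2.6270,-1.1912,-0.0725,0.6427,-0.4759,-0.8932,1.1974,0.0842,-0.6664,0.4252,-0.2746,-1.2353,0.7279,0.8941,1.0625,-1.5458,-0.4798,1.3202,1.3921,-0.1404,-0.6202,0.3811,1.7628,0.7892,1.0444,1.5649,-0.6130,-0.9867,0.1002,1.1521,-0.0591,0.8261,-1.6650,-0.0626,1.5782,1.0887,-0.5301,1.1134,-0.3608,-0.6913
MW-kg,1.2992,-0.4238,-1.3949,0.4970,1.7387,0.2777,0.3577,0.3672,0.4405,0.9290,1.5361,-2.3577,1.1074,0.7687,2.2977,-0.3746,0.9459,-1.7714,-0.3165,-1.4729,-0.1121,-0.4604,-0.7715,0.2751,-0.3936,-1.3448,0.3235,-1.9240,0.4270,1.2641,0.6727,-0.8697,0.1790,-0.5118,0.5965,0.8120,-1.2376,-0.3779,-1.0647,0.5017,-1.3597,0.8752,-0.9603,-0.9125,0.9437,-0.6055,-0.3412,-0.0103,0.0252,0.1533,-1.7621,0.5841,0.8515,-1.0629,-0.4135,0.0514,1.0613,-0.7125,-1.0457,0.0243,1.9063,0.8613,0.1177,1.2960
Nucleosome,0.1563,-0.2558,0.6224,0.4024,0.4422,-1.2307,-0.3254,-0.5354,-1.1263,0.8604,0.7663,-0.7981,-0.7937,0.7375,0.0344,-1.1979,0.5852,1.4761,0.6179,-0.0380,-1.5785,1.7904,0.8254,0.7369,0.7799,0.6955,-0.5525,-0.1029,-0.2849,-0.7980,2.6042,0.5351,0.7730,1.2074,0.7642,-1.7866,1.2217,0.1535,-0.1453,-0.6782,0.0192,1.0088,-0.5373,-0.5464,-1.1050,0.7730,0.7139,0.5320,-2.5412,0.5022,-0.0507,0.2898,0.5323,-0.0760,-1.4516,-2.3128,-1.0975,0.9948,0.3997,-0.0213,-1.8056,-1.1702,-0.9774,1.3673
Nucleosome-Rigid,0.3710,0.5871,-1.1558,0.4658,-0.6937,-0.5460,0.7061,0.6850,0.2582,-0.4361,0.9266,1.3538,-0.6504,-0.0859,0.2343,2.0053,1.1095,-1.3159,0.2841,-0.1449,0.3651,-2.4760,-1.3029,-0.1711,1.1287,-1.1352,-1.6880,-0.6710,0.0470,1.1969,-1.0787,-0.9797,0.6888,2.1125,-0.9850,0.8436,0.2201,0.1308,-1.2373,0.2482,-2.0262,1.0484,-1.0350,-1.4516,-0.8507,0.1635,1.5403,-1.3362,0.4508,0.8360,0.6290,-0.4805,1.2445,-0.7639,-0.3099,-0.3822,1.3301,-0.3651,0.6439,0.7275,1.3366,1.0696,-0.2443,-0.9898
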