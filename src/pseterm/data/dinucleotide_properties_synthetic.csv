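property,AA,AC,AG,AT,CA,CC,CG,CT,GA,GC,GG,GT,TA,TC,TG,TT
Twist,-0.7502,-0.4081,1.4506,-1.0704,-0.3208,1.8489,0.2727,-0.9023,0.6868,0.8081,0.7850,-0.1084,-1.2159,-1.4666,1.2327,-0.8422
Tilt,1.1169,0.7403,-0.2210,-0.6724,-2.0043,1.3651,-0.6790,-0.9577,0.3889,-1.3975,-0.8100,0.1237,0.6176,-0.0621,0.8529,1.5987
Roll,0.9847,-1.1333,-0.9781,-0.4650,0.8896,2.1670,1.1746,0.9946,-0.7074,-0.3230,-0.2605,-0.6500,-1.8857,-0.1129,0.2098,0.0955
Shift,1.1439,-0.5242,0.9314,-0.7257,-0.2690,-0.3618,-1.9777,0.1926,0.8181,0.6081,-1.3730,-0.0290,1.0100,1.3825,-1.5692,0.7432
Slide,-1.7600,-0.8208,-0.2751,-0.4639,2.2434,0.2321,1.4734,-0.8477,-0.5646,1.0052,-0.1157,0.6912,-1.3025,0.6566,-0.1043,-0.0473
Rise,1.9782,-1.7847,0.5821,0.4244,0.1895,-1.3471,-0.1538,-0.7468,0.7537,-0.0076,-1.3351,0.1025,1.5698,-0.4606,-0.5473,0.7830
Base stacking,1.1213,2.1597,-2.0269,0.0548,-0.7902,-1.6286,0.5626,0.0220,-0.1097,0.5360,0.4120,-0.1804,0.1953,0.6010,0.2571,-1.1859
Protein induced deformability,0.5814,0.0972,0.1573,0.3582,0.4105,-1.6105,-1.5056,1.4073,-0.6272,-1.7426,0.3972,-0.8803,-0.0382,0.1356,1.5259,1.3338
B-DNA twist,-1.5415,-1.9388,0.7118,1.0452,0.1216,-0.1741,0.2908,1.6504,-0.8101,-0.8300,0.5638,-0.0914,-0.5948,0.2817,1.7629,-0.4473
A-philicity,1.7679,0.5090,-0.3339,-0.3274,-1.1566,-0.0972,-0.3336,1.8279,0.0631,-1.7215,-1.1104,-1.3007,0.7376,0.0197,0.5035,0.9524
Propeller twist,1.1092,-0.6640,1.6853,-1.4403,-0.1900,0.6639,1.4085,-0.2028,-1.0884,-1.1768,0.5775,0.6881,-0.3605,-0.3270,0.8967,-1.5794
Duplex stability (free energy),1.2135,0.6027,-1.4759,1.1350,-0.4967,-1.6554,-0.5081,-0.8343,-0.5939,-1.3073,-0.1357,0.6676,0.6362,1.7165,0.1038,0.9320
Duplex stability (disrupt energy),-1.8993,-1.7611,0.6741,-0.6840,-0.7323,0.6770,1.0125,-0.0000,0.9287,0.0454,1.1638,0.6885,-0.5798,-1.2023,0.3441,1.3251
DNA denaturation,0.9245,-0.0216,1.4918,0.1586,-1.5503,-0.8509,-1.6318,0.0419,-0.7441,-1.5235,0.6755,0.8668,1.2689,0.0575,-0.3083,1.1450
Bending stiffness,-1.2184,-0.0700,0.9049,-0.9699,-0.0295,0.5574,-0.6884,0.8206,0.1271,0.3194,2.3594,0.8891,-0.3247,-0.9309,0.2041,-1.9502
Protein DNA twist,1.9420,-0.9089,1.2134,0.4503,-1.2260,-0.5316,-1.0289,-0.3247,-0.3826,-0.8360,0.4291,0.1877,0.2896,-1.3991,0.2227,1.9031
Stabilising energy of Z-DNA,-1.0976,0.2968,-1.5010,0.1767,-1.1406,1.5702,1.1126,-0.0005,0.9041,1.2305,0.3542,0.9931,-0.4478,-1.6812,-0.9559,0.1864
Aida_BA_transition,0.3281,-2.6978,1.4793,0.8898,0.5879,-0.1956,0.2418,-0.3023,0.1261,-1.6769,0.8392,0.5017,-0.4328,0.4760,-0.7490,0.5846
Breslauer_dG,-0.8131,0.8130,-1.2826,-1.1159,0.0372,1.1330,1.0860,0.4159,-0.0763,1.0550,0.0826,0.2405,-2.7269,0.5522,0.4519,0.1474
Breslauer_dH,0.6847,-0.6912,0.0589,2.3655,0.2894,-2.1003,-0.6269,-0.8746,-0.7200,-1.1315,0.7683,-0.2787,0.5461,0.4329,0.5102,0.7674
Breslauer_dS,0.7607,0.7228,-0.1766,-1.6475,0.6716,1.4784,1.6162,-0.3587,-0.7700,-1.1194,0.5728,-0.9224,0.2520,-0.4583,-1.5922,0.9706
Electron_interaction,-0.7299,-1.6105,-1.0744,1.8334,1.1775,-0.6722,0.1702,-0.0908,1.0014,-0.9375,0.1219,-0.3707,1.3579,-1.3377,0.3159,0.8455
Hartman_trans_free_energy,-1.7622,-0.6108,0.5905,0.7049,0.0153,2.3915,0.1566,-0.4209,-1.2692,0.8186,0.8446,-0.7925,-0.0160,-0.6848,0.9291,-0.8946
Helix-Coil_transition,0.7643,-1.0984,1.2923,1.0172,-1.9723,-0.8694,-0.0634,1.9182,-0.0391,0.1194,-0.9576,1.0628,-0.9873,-0.3035,-0.0812,0.1981
Ivanov_BA_transition,0.3634,-1.0769,1.2147,-0.5690,-0.5086,0.2283,-0.1260,-0.1499,0.6953,2.5905,0.2794,-0.6723,-0.6366,-1.2427,0.9906,-1.3801
Lisser_BZ_transition,-1.2383,0.1552,0.8185,1.3713,1.1546,-0.3776,-0.1413,0.3971,0.5885,-0.1428,-0.0283,-2.3900,-0.2250,-1.6066,0.5664,1.0985
Polar_interaction,-0.3332,-0.9224,1.3207,-1.8743,0.4986,1.2499,1.3640,0.9643,1.0812,0.5884,-0.1133,-0.3931,-0.5266,-1.2645,-1.1919,-0.4477
SantaLucia_dG,0.4607,0.3439,0.1023,2.1673,0.4046,-1.2164,-1.7580,0.5662,-0.1350,-1.7196,-0.5650,-0.5121,1.1672,-0.2801,0.9538,0.0201
SantaLucia_dH,-0.8298,0.7619,-0.0614,1.3343,-1.5972,0.7227,-0.8905,-0.8365,0.0055,1.6316,1.5575,-1.5227,-0.8632,-0.0756,0.3710,0.2925
SantaLucia_dS,0.0983,-0.6308,-1.3906,1.1690,0.9487,-1.5839,-0.7509,-0.0633,0.3660,0.0576,-1.4356,0.2488,1.0146,0.2821,-0.4975,2.1676
Stacking_energy,0.1790,-0.7329,-0.7364,-0.7141,0.7413,0.5869,0.5617,-0.0776,-0.5064,1.7149,2.6687,-0.8920,-0.7799,-0.5128,-0.5906,-0.9098
Watson-Crick_interaction,1.8612,-1.1975,-0.6653,-0.5245,-0.4087,-0.0506,-1.6397,0.9356,1.0402,-0.1101,-0.4734,0.7112,1.8873,-0.7267,-0.8357,0.1968
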