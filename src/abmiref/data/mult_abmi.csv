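sex,age_months,L,M,S,p
M,60,-0.4918,15.4386,0.0895,2.2
M,66,-0.5636,15.1110,0.0922,2.2
M,72,-0.6343,14.7741,0.0949,2.4
M,78,-0.7030,14.4144,0.0979,2.4
M,84,-0.7684,14.0174,0.1011,2.6
M,90,-0.8297,13.5933,0.1047,2.6
M,96,-0.8860,13.1675,0.1087,2.8
M,102,-0.9373,12.7832,0.1129,2.8
M,108,-0.9831,12.4651,0.1173,2.9
M,114,-1.0231,12.2089,0.1218,2.9
M,120,-1.0567,12.0023,0.1263,3.0
M,126,-1.0836,11.8326,0.1306,3.0
M,132,-1.1036,11.6934,0.1346,3.1
M,138,-1.1166,11.5986,0.1381,3.1
M,144,-1.1233,11.5928,0.1412,3.0
M,150,-1.1245,11.7107,0.1438,3.0
M,156,-1.1210,11.9687,0.1460,2.9
M,162,-1.1133,12.3574,0.1479,2.9
M,168,-1.1020,12.8576,0.1496,2.7
M,174,-1.0879,13.4674,0.1510,2.7
M,180,-1.0719,14.1891,0.1524,2.5
M,186,-1.0546,15.0236,0.1535,2.5
M,192,-1.0359,15.9401,0.1544,2.3
M,198,-1.0150,16.8787,0.1550,2.3
M,204,-0.9910,17.7793,0.1552,2.1
M,210,-0.9631,18.5937,0.1549,2.1
M,216,-0.9315,19.3111,0.1540,2.0
M,222,-0.8964,19.9401,0.1527,2.0
M,228,-0.8586,20.5068,0.1510,2.0
M,234,-0.8187,21.0334,0.1492,2.0
M,240,-0.7772,21.5366,0.1471,2.0
F,60,-0.6352,15.1841,0.0911,2.3
F,66,-0.6553,14.9207,0.0948,2.3
F,72,-0.6746,14.6464,0.0986,2.5
F,78,-0.6923,14.3385,0.1026,2.5
F,84,-0.7073,13.9695,0.1069,2.6
F,90,-0.7189,13.5426,0.1116,2.6
F,96,-0.7266,13.0856,0.1167,2.8
F,102,-0.7306,12.6601,0.1222,2.8
F,108,-0.7311,12.3132,0.1280,3.0
F,114,-0.7284,12.0620,0.1339,3.0
F,120,-0.7228,11.9165,0.1398,3.1
F,126,-0.7145,11.8864,0.1455,3.1
F,132,-0.7039,11.9847,0.1506,3.0
F,138,-0.6919,12.2430,0.1550,3.0
F,144,-0.6796,12.7195,0.1583,2.8
F,150,-0.6684,13.4403,0.1603,2.8
F,156,-0.6587,14.3865,0.1609,2.5
F,162,-0.6504,15.4798,0.1605,2.5
F,168,-0.6428,16.6158,0.1591,2.2
F,174,-0.6358,17.7094,0.1570,2.2
F,180,-0.6292,18.6986,0.1545,1.9
F,186,-0.6234,19.5560,0.1521,1.9
F,192,-0.6180,20.2647,0.1499,2.0
F,198,-0.6123,20.8158,0.1483,2.0
F,204,-0.6058,21.2096,0.1473,2.0
F,210,-0.5981,21.4565,0.1469,2.0
F,216,-0.5896,21.5852,0.1470,2.0
F,222,-0.5809,21.6314,0.1473,2.0
F,228,-0.5728,21.6344,0.1478,2.0
F,234,-0.5659,21.6221,0.1481,2.0
F,240,-0.5604,21.6115,0.1482,2.0
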