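run,cpe,csl,casein,mg,mn,protein_exp,protein_rsm,protein_ann,activity_exp,activity_rsm,activity_ann
1,45.7,23.2,6.93,0.38,0.039,935.12,1044.72,1170.4,261830,268400,262288.8
2,46.9,23.9,6.13,0.27,0.031,1318.59,1253.49,1387.45,317402,315400,312146.9
3,48.1,23.2,5.33,0.16,0.039,1693.47,1702.72,1616.0,340385,346600,340269.2
4,46.9,23.9,6.13,0.27,0.031,998.22,1253.49,1387.45,300848,315400,312146.9
5,46.9,23.9,6.13,0.05,0.031,1048.24,1331.74,1188.55,340385,332200,339497.0
6,45.7,23.2,5.33,0.16,0.039,1351.35,1063.99,1064.1,269275,281100,270420.3
7,48.1,24.6,6.93,0.38,0.039,2274.57,2196.8,2197.6,415519,412400,412461.5
8,45.7,23.2,5.33,0.38,0.039,837.47,964.7,1066.6,252400,261200,251729.8
9,46.9,23.9,6.13,0.27,0.047,1563.29,1619.47,1576.05,328151,322800,328337.1
10,45.7,24.6,6.93,0.16,0.023,1219.06,1139.99,1155.05,310405,312700,310336.8
11,45.7,24.6,5.33,0.38,0.039,1227.46,1287.64,1212.35,311937,309400,311970.5
12,48.1,23.2,6.93,0.38,0.023,1948.38,1948.43,1893.25,367211,378000,377815.2
13,45.7,23.2,6.93,0.16,0.039,1266.35,1211.33,1167.9,296958,288300,296811.7
14,46.9,23.9,6.13,0.27,0.031,1355.33,1253.49,1387.45,319375,315400,312146.9
15,46.9,23.9,6.13,0.27,0.031,1328.21,1253.49,1387.45,318301,315400,312146.9
16,48.1,24.6,5.33,0.38,0.023,1893.29,1978.58,1935.15,372208,373800,372361.0
17,46.9,23.9,7.73,0.27,0.031,1436.47,1490.05,1510.9,320929,324000,321177.7
18,46.9,23.9,6.13,0.27,0.031,1187.41,1253.49,1387.45,306867,315400,312146.9
19,46.9,23.9,4.53,0.27,0.031,1121.99,1243.1,1263.95,306150,306800,306863.6
20,48.1,24.6,6.93,0.38,0.023,1983.25,2038.91,2039.0,384720,381000,384641.0
21,46.9,23.9,6.13,0.27,0.031,1192.47,1253.49,1387.45,306992,315400,312146.9
22,49.3,23.9,6.13,0.27,0.031,2413.46,2643.58,2702.05,447379,456000,457844.1
23,44.5,23.9,6.13,0.27,0.031,994.46,939.02,997.5,299714,293600,298634.8
24,45.7,24.6,5.33,0.16,0.023,973.46,936.68,1051.25,296385,305400,296495.7
25,45.7,24.6,6.93,0.38,0.039,1522.12,1424.82,1316.2,323043,316700,325167.7
26,45.7,24.6,5.33,0.16,0.039,1289.64,1265.05,1209.85,312877,312100,298499.7
27,46.9,22.5,6.13,0.27,0.031,1076.47,1311.77,1214.1,303431,295200,303242.4
28,48.1,23.2,5.33,0.38,0.039,2018.53,1932.93,1948.0,390353,376600,387310.8
29,48.1,24.6,5.33,0.16,0.039,1819.38,1783.19,1761.8,349332,357900,349119.9
30,46.9,23.9,6.13,0.49,0.031,1838.35,1729.53,1586.35,354050,364700,353659.7
31,48.1,23.2,5.33,0.38,0.023,2093.4,1945.25,1789.4,382518,370800,379807.3
32,45.7,23.2,5.33,0.38,0.023,1064.18,954.37,907.95,288727,280100,288726.9
33,48.1,23.2,6.93,0.16,0.039,1978.46,1774.4,1719.85,363476,353900,354450.7
34,45.7,24.6,5.33,0.38,0.023,1078.29,1108.29,1053.75,303449,302800,303203.2
35,48.1,24.6,6.93,0.16,0.039,1884.38,1912.01,1865.6,357922,365200,357339.0
36,48.1,24.6,5.33,0.16,0.023,1653.57,1477.48,1603.15,337360,326600,329860.2
37,45.7,23.2,5.33,0.16,0.023,780.93,904.66,905.45,298760,300000,299603.1
38,46.9,23.9,6.13,0.27,0.031,1320.48,1253.49,1387.45,318272,315400,312146.9
39,48.1,23.2,5.33,0.16,0.023,1658.48,1566.04,1457.4,339840,340900,339455.5
40,48.1,23.2,6.93,0.38,0.039,1937.27,1937.29,2051.85,383862,383800,382572.9
41,46.9,23.9,6.13,0.27,0.031,1212.47,1253.49,1387.45,311419,315400,312146.9
42,45.7,23.2,6.93,0.16,0.023,1129.31,1050.81,1009.3,306356,307200,306191.7
43,46.9,23.9,6.13,0.27,0.015,1123.73,1242.23,1198.8,306154,308100,306589.0
44,48.1,23.2,6.93,0.16,0.023,1708.39,1636.53,1561.25,342792,348100,342818.5
45,45.7,23.2,6.93,0.38,0.023,1116.28,1033.21,1011.8,293529,287300,293509.2
46,46.9,25.3,6.13,0.27,0.031,1719.08,1658.46,1560.8,343103,335600,343017.9
47,48.1,24.6,6.93,0.16,0.023,1711.46,1605.11,1707.0,342807,333800,346111.9
48,45.7,24.6,6.93,0.38,0.023,1125.08,1244.28,1157.55,306881,310000,317813.1
49,48.1,24.6,5.33,0.38,0.039,2148.36,2135.29,2093.8,408482,405100,406157.9
50,45.7,24.6,6.93,0.16,0.039,1342.46,1469.53,1313.7,318496,319300,318389.3
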