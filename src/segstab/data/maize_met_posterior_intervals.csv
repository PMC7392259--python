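prior_set,genotype,b0_lower,b0_mean,b0_upper,b1_lower,b1_mean,b1_upper,b12_lower,b12_mean,b12_upper,s2d_lower,s2d_mean,s2d_upper,r2
M1,30A68HX,9316.00,9465.56,9911.00,0.79,0.90,1.24,1.53,1.79,2.58,841275.00,1115511.90,2114100.00,77.44
M1,30A16HX,9295.00,9431.87,9838.03,1.44,1.54,1.85,1.72,1.95,2.67,701600.00,930323.50,1763075.00,89.85
M1,2B707HX,9134.00,9288.44,9748.03,1.05,1.17,1.52,1.17,1.44,2.25,896975.00,1189343.80,2254100.00,80.12
M1,2B587HX,9088.00,9200.56,9536.00,1.24,1.32,1.58,1.26,1.45,2.04,477375.00,632954.50,1199075.00,90.03
M1,30A37HX,9072.00,9195.19,9560.03,1.14,1.23,1.51,0.75,0.96,1.61,566600.00,751357.90,1424050.00,86.00
M1,2B604HX,9052.00,9194.07,9615.03,1.02,1.13,1.45,1.57,1.82,2.56,752675.00,998071.40,1891100.00,83.58
M1,2B710HX,9067.00,9181.73,9524.00,0.98,1.07,1.33,0.80,1.00,1.60,496300.00,658055.00,1247050.00,84.56
M1,30A95HX,8894.00,9075.28,9615.03,1.08,1.22,1.63,1.17,1.48,2.43,1237000.00,1640324.80,3108150.00,76.18
M1,P4285HX,8915.00,9055.94,9474.03,0.52,0.62,0.94,0.79,1.03,1.77,743475.00,985850.50,1868100.00,63.06
M1,30F53HR,8816.00,9009.92,9585.03,0.74,0.88,1.32,-0.16,0.18,1.19,1404000.00,1862281.10,3529150.00,56.08
M1,2B433HX,8871.75,8960.69,9226.00,0.97,1.04,1.24,0.79,0.95,1.42,298500.00,395843.90,750037.50,89.45
M1,20A55HR,8733.00,8834.60,9136.00,1.14,1.22,1.45,0.56,0.73,1.26,385100.00,510603.50,967545.00,89.34
M1,20A78HX,8652.00,8817.59,9311.03,1.06,1.18,1.56,0.59,0.88,1.75,1034000.00,1370711.40,2597125.00,75.88
M1,DKB370,8610.00,8759.79,9184.00,1.11,1.21,1.53,1.24,1.49,2.27,788600.00,1055663.80,2012125.00,83.03
M1,2B688HX,8612.00,8757.44,9190.00,0.82,0.93,1.26,0.31,0.56,1.32,792775.00,1051201.20,1992100.00,71.56
M1,AG8041YG,8601.00,8744.84,9173.03,0.73,0.84,1.17,0.56,0.81,1.57,779900.00,1034193.00,1960075.00,69.57
M1,30K73H,8578.00,8732.15,9190.00,0.98,1.09,1.44,0.79,1.06,1.86,888300.00,1177882.70,2232100.00,76.85
M1,DKB330,8295.00,8475.94,9015.03,0.90,1.03,1.44,0.81,1.12,2.07,1233000.00,1634763.20,3098125.00,69.38
M1,AS1596YG,8200.00,8363.82,8851.00,0.73,0.85,1.22,0.80,1.08,1.94,1006000.00,1333766.70,2527125.00,66.98
M1,BM820,8140.00,8269.68,8654.00,0.90,1.00,1.29,-0.27,-0.04,0.63,626600.00,830832.00,1574075.00,77.21
M1,AS1555YG,7877.00,7996.51,8365.03,0.65,0.74,1.02,1.67,1.88,2.54,580050.00,777663.90,1477075.00,80.68
M1,Statusvip,7495.00,7780.31,8629.03,0.75,0.96,1.61,0.42,0.92,2.41,3056000.00,4052797.70,7680325.00,46.09
M1,BRS2022,7453.00,7576.31,7944.03,0.63,0.72,1.00,0.09,0.30,0.95,574200.00,761371.30,1443050.00,67.12
M1,30A91HX,7293.00,7487.64,8067.00,0.42,0.56,1.00,-0.40,-0.07,0.96,1424000.00,1887726.00,3577175.00,37.25
M1,BRS2020,7346.00,7466.96,7826.03,0.40,0.49,0.76,-0.17,0.04,0.67,547575.00,726058.60,1376050.00,50.86
M2,30A68HX,9464.00,9464.00,9464.00,0.81,0.90,1.17,1.59,1.80,2.41,679400.00,863019.30,1503000.00,76.90
M2,30A16HX,9430.00,9430.00,9430.00,1.46,1.54,1.80,1.77,1.96,2.53,576100.00,731857.10,1274025.00,89.75
M2,2B707HX,9287.00,9287.00,9287.00,1.08,1.17,1.45,1.24,1.45,2.07,720600.00,915214.00,1593025.00,79.60
M2,2B587HX,9199.00,9199.00,9199.00,1.25,1.32,1.54,1.29,1.46,1.95,409675.00,520498.60,907202.50,90.00
M2,30A37HX,9194.00,9194.00,9194.00,1.16,1.23,1.46,0.79,0.97,1.49,475900.00,604773.60,1054000.00,85.78
M2,2B604HX,9193.00,9192.79,9193.00,1.04,1.13,1.39,1.63,1.82,2.41,613900.00,779879.20,1358000.00,83.29
M2,2B710HX,9180.00,9180.33,9181.00,0.99,1.07,1.29,0.84,1.01,1.50,423700.00,538376.70,937920.00,84.36
M2,30A95HX,9073.00,9073.00,9073.00,1.11,1.22,1.54,1.25,1.49,2.19,971375.00,1233075.60,2145000.00,75.36
M2,P4285HX,9054.00,9054.01,9054.00,0.54,0.62,0.88,0.84,1.04,1.62,607100.00,771220.60,1343000.00,61.97
M2,30F53HR,9008.00,9008.00,9008.00,0.77,0.88,1.22,-0.06,0.19,0.92,1095000.00,1388961.00,2415000.00,53.95
M2,2B433HX,8960.00,8960.00,8960.00,0.98,1.04,1.22,0.81,0.95,1.37,276400.00,351203.30,612807.50,89.50
M2,20A55HR,8833.00,8833.58,8834.00,1.15,1.22,1.41,0.58,0.74,1.19,340900.00,433232.50,755505.00,89.29
M2,20A78HX,8816.00,8816.00,8816.00,1.08,1.18,1.48,0.67,0.89,1.55,821775.00,1043252.90,1815025.00,75.06
M2,DKB370,8756.00,8756.00,8756.00,0.85,0.93,1.20,0.37,0.57,1.16,643500.00,817506.60,1424000.00,70.66
M2,2B688HX,8755.00,8755.00,8755.00,1.12,1.21,1.48,1.29,1.49,2.09,649075.00,824492.50,1436000.00,82.39
M2,AG8041YG,8743.00,8743.00,8743.00,0.76,0.84,1.11,0.62,0.82,1.41,634000.00,805464.40,1403000.00,68.65
M2,30K73H,8730.00,8730.26,8731.00,1.00,1.10,1.37,0.86,1.07,1.69,714275.00,907119.60,1579025.00,76.18
M2,DKB330,8474.00,8474.00,8474.00,0.93,1.04,1.35,0.89,1.13,1.83,968275.00,1229178.30,2138000.00,68.21
M2,AS1596YG,8362.00,8362.00,8362.00,0.76,0.86,1.15,0.87,1.09,1.74,801200.00,1017188.20,1770000.00,65.83
M2,BM820,8268.00,8268.00,8268.00,0.92,1.00,1.24,-0.22,-0.04,0.51,520500.00,661250.80,1152025.00,76.53
M2,AS1555YG,7990.00,7990.44,7991.00,0.67,0.74,0.98,1.70,1.88,2.41,496000.00,630259.80,1099000.00,80.08
M2,Statusvip,7777.00,7777.00,7777.00,0.82,0.97,1.41,0.61,0.93,1.86,2302000.00,2913389.60,5059000.00,42.69
M2,BRS2022,7575.00,7575.00,7575.00,0.64,0.72,0.95,0.13,0.31,0.84,481600.00,611894.50,1067000.00,66.20
M2,30A91HX,7485.00,7485.65,7486.00,0.45,0.56,0.90,-0.30,-0.06,0.68,1109000.00,1406803.70,2445025.00,33.92
M2,BRS2020,7466.00,7466.00,7466.00,0.42,0.49,0.72,-0.13,0.04,0.56,461800.00,586780.90,1022025.00,49.27
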