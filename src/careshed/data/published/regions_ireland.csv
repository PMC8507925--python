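region,n_0_30,pct_0_30,n_30_60,pct_30_60,n_over_60,pct_over_60,total
Longford,40863,99.97,10,0.03,0,0.00,40873
Westmeath,88730,99.95,40,0.05,0,0.00,88770
Meath,193496,99.21,1248,0.64,300,0.15,195044
Dublin,1333512,98.97,2862,0.21,10985,0.82,1347359
Kildare,218193,98.06,4311,1.94,0,0.00,222504
Kilkenny,93609,94.33,5623,5.67,0,0.00,99232
Laois,79071,93.36,5626,6.64,0,0.00,84697
Limerick,180987,92.86,13912,7.14,0,0.00,194899
Cavan,68733,90.23,7443,9.77,0,0.00,76176
Tipperary,143291,89.81,16262,10.19,0,0.00,159553
Louth,115582,89.68,12104,9.39,1198,0.93,128884
Roscommon,54182,83.95,10362,16.05,0,0.00,64544
Sligo,54058,82.49,10290,15.70,1186,1.81,65535
Galway,198101,76.77,47708,18.49,12249,4.75,258058
Kerry,112275,76.01,26448,17.91,8983,6.08,147707
Offaly,59015,75.70,18946,24.30,0,0.00,77961
Clare,89232,75.10,28547,24.03,1038,0.87,118817
Cork,404044,74.43,132674,24.44,6150,1.13,542868
Wexford,108421,72.41,39229,26.20,2072,1.38,149722
Waterford,84117,72.41,31580,27.18,479,0.41,116176
Mayo,86514,66.29,34504,26.44,9489,7.27,130507
Donegal,98452,61.84,54249,34.08,6491,4.08,159192
Wicklow,80169,56.29,60638,42.58,1617,1.14,142425
Leitrim,16896,52.73,15146,47.27,3,0.01,32044
Carlow,13769,24.19,43163,75.81,0,0.00,56932
Monaghan,4601,7.50,56434,91.93,351,0.57,61386
Ireland,4019915,84.42,679360,14.27,62590,1.31,4761865
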