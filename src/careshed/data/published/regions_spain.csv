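region,n_0_30,pct_0_30,n_30_60,pct_30_60,n_over_60,pct_over_60,total
Ciudad Autónoma de Melilla,85010,98.41,0,0.00,1374,1.59,86384
Ciudad Autónoma de Ceuta,83399,97.95,0,0.00,1745,2.05,85144
Comunidad de Madrid,6438968,97.89,138417,2.10,693,0.01,6578079
Cantabria,546052,94.11,27173,4.68,7004,1.21,579859
Principado de Asturias,959820,93.35,59033,5.74,9391,0.91,1028244
Región de Murcia,1371193,92.74,105734,7.15,1582,0.11,1478509
País Vasco,1925815,87.57,270928,12.32,2345,0.11,2199088
Cataluña,6417156,84.44,1099479,14.47,83430,1.10,7599736
Islas Baleares,881288,78.07,87701,7.77,159920,14.17,1128908
Galicia,2103396,77.85,529309,19.59,69037,2.56,2701743
Extremadura,797488,74.33,236666,22.06,38709,3.61,1072863
Comunidad Valencia,3684580,74.23,1192828,24.03,86295,1.74,4963703
Andalucía,6138419,73.21,2032086,24.24,213903,2.55,8384408
Aragón,887355,67.80,298456,22.81,122916,9.39,1308312
Comunidad Foral de Navarra,436546,67.41,198655,30.68,12353,1.91,647404
La Rioja,211313,66.94,98979,31.35,5382,1.70,315675
Canarias,1385526,65.12,410927,19.31,331232,15.57,2127685
Castilla y León,1474924,61.22,740966,30.76,193274,8.02,2409164
Castilla-La Mancha,1199464,59.18,679131,33.51,148212,7.31,2026807
Spain,37027713,79.25,8206264,17.56,1488747,3.19,46721715
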