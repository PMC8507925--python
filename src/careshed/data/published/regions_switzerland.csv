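region,n_0_30,pct_0_30,n_30_60,pct_30_60,n_over_60,pct_over_60,total
Zug,125421,100.00,0,0.00,0,0.00,125421
Basel-Stadt,193908,100.00,0,0.00,0,0.00,193908
Zürich,1504214,99.99,131,0.01,2,0.00,1504347
Aargau,670597,99.94,390,0.06,0,0.00,670987
Genève,494638,99.88,613,0.12,0,0.00,495251
Basel-Landschaft,286615,99.86,408,0.14,0,0.00,287023
Thurgau,273036,99.72,388,0.14,376,0.14,273800
Fribourg,313980,99.65,1086,0.34,9,0.00,315075
Appenzell Ausserhoden,54738,99.20,440,0.80,0,0.00,55178
Nidwalden,42409,98.69,348,0.81,213,0.50,42970
St. Gallen,493968,97.88,10167,2.01,552,0.11,504687
Vaud,773376,97.51,19584,2.47,168,0.02,793128
Luzern,393541,96.81,12960,3.19,0,0.00,406501
Solothurn,261258,96.25,10173,3.75,0,0.00,271431
Appenzell Innerrhoden,15479,96.11,626,3.89,0,0.00,16105
Neuchâtel,169447,95.21,8517,4.79,0,0.00,177964
Schwyz,148908,94.66,6238,3.97,2157,1.37,157303
Ticino,334214,94.49,15007,4.24,4487,1.27,353708
Bern,948478,91.99,78635,7.63,4008,0.39,1031121
Schaffhausen,70232,86.33,11121,13.67,0,0.00,81353
Obwalden,31750,84.50,5394,14.36,430,1.14,37574
Uri,29407,81.01,4931,13.58,1961,5.40,36299
Valais,267645,78.38,63560,18.61,10262,3.01,341467
Graubünden,117067,59.16,40717,20.58,40102,20.27,197886
Glarus,9128,22.62,28747,71.24,2475,6.13,40350
Jura,8016,10.94,64283,87.71,993,1.35,73292
Switzerland,8031470,94.66,384464,4.53,68195,0.81,8484129
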