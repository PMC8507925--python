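country,band,population,percent
Ireland,0-30,4019915,84.42
Ireland,30-60,679360,14.27
Ireland,over 60,62590,1.31
Spain,0-30,37027707,79.25
Spain,30-60,8206486,17.56
Spain,over 60,1488787,3.19
Switzerland,0-30,8031471,94.66
Switzerland,30-60,384464,4.53
Switzerland,over 60,68195,0.81
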