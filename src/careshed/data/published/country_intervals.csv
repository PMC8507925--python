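country,interval,population
Ireland,0-10,1884201
Ireland,10-20,1273031
Ireland,20-30,862683
Ireland,30-40,446579
Ireland,40-50,175881
Ireland,50-60,56899
Ireland,60-90,27414
Ireland,over 90,35177
Spain,0-10,17239404
Spain,10-20,12966726
Spain,20-30,6821577
Spain,30-40,4691593
Spain,40-50,2402829
Spain,50-60,1112064
Spain,60-90,876034
Spain,over 90,612753
Switzerland,0-10,3941773
Switzerland,10-20,2967508
Switzerland,20-30,1122189
Switzerland,30-40,244503
Switzerland,40-50,93006
Switzerland,50-60,46955
Switzerland,60-90,43112
Switzerland,over 90,25083
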