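ligand,L0_uM,replicate,ab_free,ab_bound
dC5,5,1,65099625,18794425
dC5,5,2,68544428,23145457
dC5,5,3,78972474,25147375
dC5,10,1,47825661,27545273
dC5,10,2,46350320,31619901
dC5,10,3,43525177,30298740
dC5,20,1,30107821,45426668
dC5,20,2,23925313,39437219
dC5,20,3,21135712,32082196
dC5,40,1,7997701,28282560
dC5,40,2,5843389,21520555
dC5,40,3,6539939,23879435
dC2AC2,5,1,51636536,14389383
dC2AC2,5,2,42294232,12579820
dC2AC2,5,3,42446013,13959865
dC2AC2,10,1,36684700,21676041
dC2AC2,10,2,24124562,15498871
dC2AC2,10,3,32045216,21127649
dC2AC2,20,1,15246271,25179158
dC2AC2,20,2,18296917,33389720
dC2AC2,20,3,20579066,38415859
dC2AC2,40,1,4941720,26053318
dC2AC2,40,2,5332933,30339897
dC2AC2,40,3,4343254,23458825
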