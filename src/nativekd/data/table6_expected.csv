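ligand,L0_uM,replicate,R,Kd_uM
dC5,5,1,0.29,-14.4
dC5,5,2,0.34,-15.8
dC5,5,3,0.32,-15.3
dC5,10,1,0.58,-8.6
dC5,10,2,0.68,-9.7
dC5,10,3,0.70,-9.7
dC5,20,1,1.51,-3.0
dC5,20,2,1.65,-3.3
dC5,20,3,1.52,-3.1
dC5,40,1,3.54,2.3
dC5,40,2,3.68,2.1
dC5,40,3,3.65,2.2
dC2AC2,5,1,0.28,-14.0
dC2AC2,5,2,0.30,-14.7
dC2AC2,5,3,0.33,-15.6
dC2AC2,10,1,0.59,-8.8
dC2AC2,10,2,0.64,-9.3
dC2AC2,10,3,0.66,-9.5
dC2AC2,20,1,1.65,-3.3
dC2AC2,20,2,1.82,-3.5
dC2AC2,20,3,1.87,-3.6
dC2AC2,40,1,5.27,1.1
dC2AC2,40,2,5.69,0.9
dC2AC2,40,3,5.40,1.0
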