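sample,rnase_stock_uL,water_uL,buffer_uL,oligo_stock_uL,total_uL,L0_uM,P0_uM,replicates
1,10,40,50,0,100,0,40.9,6
2,10,37.5,50,2.5,100,5,40.9,3
3,10,35,50,5,100,10,40.9,3
4,10,30,50,10,100,20,40.9,3
5,10,20,50,20,100,40,40.9,3
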