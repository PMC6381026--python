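x,obs,P1,P2,P3,P4,P5,P6,P7,P8,P9,P10
1,3,2,4,3,4,10,5,7,3,10,5
1,7,7,1,4,3,4,2,4,3,7,7
1,4,4,4,4,5,4,4,4,7,5,3
1,1,10,10,3,3,1,10,5,5,7,10
2,4,1,7,7,1,2,1,10,4,4,4
2,3,4,3,1,7,5,3,3,2,2,4
2,1,1,2,10,4,3,4,7,1,1,3
2,10,1,1,2,1,3,7,3,7,1,1
3,1,5,5,7,10,1,3,1,1,4,1
3,7,3,3,5,2,7,1,1,4,3,1
3,2,7,7,1,1,1,7,2,10,3,2
3,5,3,1,1,7,7,1,1,1,1,7
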