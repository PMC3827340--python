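run,label,ginsenosides,berberine,jasminoidin,total
1,GBJ,13.64,9.09,2.27,25
2,G,25,0,0,25
3,B,0,25,0,25
4,J,0,0,25,25
5,GB,12.5,12.5,0,25
6,BJ,0,12.5,12.5,25
7,GJ,12.5,0,12.5,25
8,GBJ,2.73,1.82,0.45,5
9,G,5,0,0,5
10,B,0,5,0,5
11,J,0,0,5,5
12,GB,2.5,2.5,0,5
13,BJ,0,2.5,2.5,5
14,GJ,2.5,0,2.5,5
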