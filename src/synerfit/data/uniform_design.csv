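run,level_ginsenosides,level_berberine,level_jasminoidin,ginsenosides,berberine,jasminoidin,total
1,3,7,9,3.273,3.636,1.091,8.000
2,6,4,8,4.909,2.545,1.000,8.455
3,9,1,7,6.545,0.000,0.909,7.455
4,2,8,6,2.727,4.000,0.818,7.545
5,5,5,5,4.364,2.909,0.727,8.000
6,8,2,4,6.000,1.818,0.636,8.636
7,1,9,3,0.000,4.364,0.545,4.909
8,4,6,2,3.818,3.273,0.455,7.545
9,7,3,1,5.455,2.182,0.000,7.636
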