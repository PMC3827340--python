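component,level,dose
ginsenosides,1,0.000
ginsenosides,2,2.727
ginsenosides,3,3.273
ginsenosides,4,3.818
ginsenosides,5,4.364
ginsenosides,6,4.909
ginsenosides,7,5.455
ginsenosides,8,6.000
ginsenosides,9,6.545
berberine,1,0.000
berberine,2,1.818
berberine,3,2.182
berberine,4,2.545
berberine,5,2.909
berberine,6,3.273
berberine,7,3.636
berberine,8,4.000
berberine,9,4.364
jasminoidin,1,0.000
jasminoidin,2,0.455
jasminoidin,3,0.545
jasminoidin,4,0.636
jasminoidin,5,0.727
jasminoidin,6,0.818
jasminoidin,7,0.909
jasminoidin,8,1.000
jasminoidin,9,1.091
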