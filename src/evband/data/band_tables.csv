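level,lower_kg,upper_kg,dose_mg
1.25,0,45,50
1.25,45,55,60
1.25,55,65,70
1.25,65,75,80
1.25,75,95,90
1.25,95,,100
1.0,0,45,40
1.0,45,55,50
1.0,55,65,60
1.0,65,75,60
1.0,75,95,70
1.0,95,,80
0.75,0,45,30
0.75,45,55,40
0.75,55,65,40
0.75,65,75,50
0.75,75,95,50
0.75,95,,60
0.5,0,45,20
0.5,45,55,20
0.5,55,65,30
0.5,65,75,30
0.5,75,95,40
0.5,95,,40
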