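time_days,csc_percent,ratio
0,96.2,0.0395
28,84.9,0.1779
52,53.2,0.8797
70,25.9,2.8610
84,19.7,4.0761
92,11.2,7.9286
105,4.3,22.2558
117,2.7,36.0370
128,2.0,49.0000
137,1.5,65.6667
150,1.6,61.5000
160,1.5,65.6667
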