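muscle,L2,L3,L4,L5,S1,S2,S3
R-VL,0.5,1.0,1.0,0.0,0.0,0.0,0.0
R-RF,0.5,1.0,1.0,0.0,0.0,0.0,0.0
R-VM,0.5,1.0,1.0,0.0,0.0,0.0,0.0
R-BF,0.0,0.0,0.0,1.0,1.0,0.5,0.0
R-ST,0.0,0.0,0.0,1.0,1.0,0.5,0.0
R-TA,0.0,0.0,1.0,1.0,0.5,0.0,0.0
R-GL,0.0,0.0,0.0,0.5,1.0,1.0,0.5
L-VL,0.5,1.0,1.0,0.0,0.0,0.0,0.0
L-RF,0.5,1.0,1.0,0.0,0.0,0.0,0.0
L-VM,0.5,1.0,1.0,0.0,0.0,0.0,0.0
L-BF,0.0,0.0,0.0,1.0,1.0,0.5,0.0
L-ST,0.0,0.0,0.0,1.0,1.0,0.5,0.0
L-TA,0.0,0.0,1.0,1.0,0.5,0.0,0.0
L-GL,0.0,0.0,0.0,0.5,1.0,1.0,0.5
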