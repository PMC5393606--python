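class,Clayey,Loamy,Sandy,Shallow sandy,Deep sand
Clayey,5,0,0,0,0
Loamy,0,32,2,0,2
Sandy,0,3,79,1,3
Shallow sandy,0,0,1,14,0
Deep sand,0,2,4,1,27
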