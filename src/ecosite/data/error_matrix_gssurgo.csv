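class,Clayey,Loamy,Sandy,Shallow sandy,Deep sand
Clayey,0,0,0,0,0
Loamy,5,27,26,1,1
Sandy,0,10,59,10,31
Shallow sandy,0,0,1,5,0
Deep sand,0,0,0,0,0
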