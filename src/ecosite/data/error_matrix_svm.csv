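class,Clayey,Loamy,Sandy,Shallow sandy,Deep sand
Clayey,41,30,0,0,0
Loamy,58,573,183,21,83
Sandy,1,353,1971,207,396
Shallow sandy,0,0,95,113,11
Deep sand,0,114,251,59,410
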