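c1,c2,t1,t2
7,4,0,107
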