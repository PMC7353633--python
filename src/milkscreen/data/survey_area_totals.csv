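area,n_total
E,8
N,13
NW,15
NE,2
S,14
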