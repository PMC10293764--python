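Element,Max
C,10
H,12
N,3
O,3
S,1
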