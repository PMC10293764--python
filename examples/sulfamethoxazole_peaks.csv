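mz,intensity
65.0382,1
68.049,1
92.0496,1
93.0575,1
99.0562,1
108.046,1
110.0605,1
146.071,1
147.0791,1
148.0864,1
156.0119,1
157.0146,1
158.0078,1
160.0873,1
188.0822,1
254.0603,1
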