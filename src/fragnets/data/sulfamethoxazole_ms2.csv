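mz,intensity,reference
65.0382,1,C5H5+
68.049,1,C4NH6+
92.0496,1,C6NH6+
93.0575,1,C6NH7+
99.0562,1,C4ON2H7+
108.046,1,C6ONH6+
110.0605,1,C6ONH8+
146.071,1,C8N3H8+
147.0791,1,C8N3H9+
148.0864,1,C8N3H10+
156.0119,1,C6SO2NH6+
157.0146,1,–
158.0078,1,–
160.0873,1,C9N3H10+
188.0822,1,C10ON3H10+
254.0603,1,C10SO3N3H12+
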