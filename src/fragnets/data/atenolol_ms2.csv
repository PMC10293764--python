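mz,intensity,reference
56.0491,1,C3NH6+
72.0804,1,C4NH10+
74.0597,1,C3ONH8+
98.0973,1,C6NH12+
116.1079,1,C6ONH14+
133.0651,1,C9OH9+
145.0648,1,C10OH9+
162.0914,1,C10ONH12+
164.0705,1,C9O2NH10+
173.0597,1,C11O2H9+
178.0867,1,C10O2NH12+
180.1022,1,C10O2NH14+
190.0866,1,C11O2NH12+
191.0898,1,–
208.0976,1,C11O3NH14+
225.1239,1,C11O3N2H17+
267.1709,1,C14O3N2H23+
268.1747,1,–
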