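mz,intensity,reference
194.0964,1,C14NH12+
237.102,1,C15ON2H13+
238.1052,1,–
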