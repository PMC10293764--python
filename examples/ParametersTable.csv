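Parameter,Value
NoiseTresInt,1000
ionization,+
default_tol_ppm,10
gap_ppm,10
confidence_level,0.95
intensity_floor_pct,1
network_mode,auto
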