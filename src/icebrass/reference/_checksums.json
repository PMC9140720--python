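{
 "trussell_west_coefficients.csv": "57de3f1c6ab3c475b56fabf5484d17c14a89dd03e6b75397cea183d2ee8c64f4",
 "west_lx_levels_synthetic.csv": "fec9fe28ab38ff05ecd2bd486f29b70770bb529b3dc54743a720711c2ff1a331"
}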