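2.567865472192142e+00	4.065620619375109e-01
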