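reference	cage1	cage2	cage3	clasp1	clasp2
HP1_type_reference_synthetic	2	23	26	37	46
Pc_type_reference_synthetic	2	23	26	37	46
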