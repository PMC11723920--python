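>HP1_type_reference_synthetic
EEYVVEKVLDRRVVNGKVEYLLKWKGYSDEDNTWEPEDNLDCPELIEEFEDSDKE
>Pc_type_reference_synthetic
GSYKVEKILGARVRNGKVEYLVKWKGWSPKYNTWEPEVNILDPRLVAKYEKKARK
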