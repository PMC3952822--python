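scenario,quantity,unit,n,mean,sem
normal,hdl_c,mg/dL,86,52,1
normal,apoa1,mg/dL,86,139,4
cetp_het,hdl_c,mg/dL,40,75,4
cetp_het,apoa1,mg/dL,40,152,5
cetp_hom,hdl_c,mg/dL,23,166,7
cetp_hom,apoa1,mg/dL,23,232,8
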