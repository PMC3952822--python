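scenario,quantity,unit,n,mean,sem
normal,ldl_ce,mg/dL,10,83,3
normal,vldl_ce,mg/dL,10,5,1
cetp_het,ldl_ce,mg/dL,23,72,9
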