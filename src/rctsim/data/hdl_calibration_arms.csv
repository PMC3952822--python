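scenario,quantity,unit,study,n,mean,sd
normal,hdl_c,mg/dL,A,16,52.9,13.9
normal,hdl_c,mg/dL,B,20,50,8
normal,hdl_c,mg/dL,C,50,52,14
normal,apoa1,mg/dL,A,16,124,21
normal,apoa1,mg/dL,B,20,140.9,16.1
normal,apoa1,mg/dL,C,50,144,29
cetp_het,hdl_c,mg/dL,A,20,66,15
cetp_het,hdl_c,mg/dL,B,15,84,25
cetp_het,hdl_c,mg/dL,C,5,85,26
cetp_het,apoa1,mg/dL,A,20,149,43
cetp_het,apoa1,mg/dL,B,15,155.3,22.1
cetp_het,apoa1,mg/dL,C,5,154,25
cetp_hom,hdl_c,mg/dL,A,10,163.7,39
cetp_hom,hdl_c,mg/dL,B,4,193,28
cetp_hom,hdl_c,mg/dL,C,9,157,29
cetp_hom,apoa1,mg/dL,A,10,213,47
cetp_hom,apoa1,mg/dL,B,4,233.5,22.3
cetp_hom,apoa1,mg/dL,C,9,252,25
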