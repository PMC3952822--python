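parameter,unit,prior_mean,prior_sd,informative,posterior_mean,posterior_sd
s_apoa1,mg/dL/day,27.44,1.18,1,28.46,1.13
k_kidney,pool/day,5.19,2.60,1,2.42,0.78
k_diss,pool/day,174,312,1,170,191
k_abca1,pool/day,96.24,17.55,1,95.18,15.73
gamma,1,7.55,3.94,1,10.17,2.19
k_hv,pool/day,1.47,0.58,1,1.49,0.24
k_hl,pool/day,5.47,2.05,1,6.92,0.81
k_lh,pool/day,1.98,0.70,1,2.89,0.34
k_vl,pool/day,7.52,0.94,1,7.70,0.84
s_vldl_ce,mg/dL/day,0.96,0.46,1,1.50,0.45
k_ev,pool/day,0.88,0.37,1,1.30,0.35
k_el,pool/day,0.67,0.08,1,0.64,0.07
k_srb1,pool/day,0.31,0.12,1,0.60,0.08
ku0,pool/day,0.14,0.026,1,0.13,0.022
ku1,pool/day/nm,0,0,0,-0.016,0.004
k_fus,1/(mmol/dL),0,0,0,5000,1544
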