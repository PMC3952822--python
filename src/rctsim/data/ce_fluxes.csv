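flux,unit,mean,sem
hdl_to_vldl,mg/dL/day,64,2
hdl_to_ldl,mg/dL/day,268,51
ldl_to_hdl,mg/dL/day,266,52
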