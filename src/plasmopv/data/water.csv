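wavelength_nm,n,k
250,1.3300000000000001,0
810,1.3300000000000001,0
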