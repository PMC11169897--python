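wavelength_nm,a_radius_nm,fill_fraction,intensity_mW_mm2,with_k,jsc_a_m2,voc_v,ff_pct,pce_pct
453,,0.0,0.33,0,9.5,0.67,78.5,1.5
453,,0.0,0.26,0,7.5,0.67,75.5,1.4
250,,0.0,0.33,0,23,0.68,78.0,3.5
250,,0.0,0.26,0,19,0.68,77.5,3.8
453,7.5,0.05,0.33,1,25,0.68,76.5,4.0
453,10.0,0.05,0.26,1,25,0.68,76.5,5.0
453,7.5,0.075,0.33,1,30,0.685,78.0,4.8
453,10.0,0.075,0.26,1,32,0.685,75.2,6.3
453,7.5,0.1,0.33,1,35,0.69,76.5,5.6
453,10.0,0.1,0.26,1,38,0.69,80.0,8.0
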