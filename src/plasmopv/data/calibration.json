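{
 "collection_efficiency": 0.3090923671895523,
 "layer_effective_path_nm": 116.57751072729452,
 "np_channel_path_cm": 3.080577015326252e-07,
 "kappa_a": 0.8009181420085781,
 "kappa_k": 0.43517709663227155,
 "anchors": {
  "bare_jsc_453_a_m2": 7.5,
  "bare_jsc_250_a_m2": 19.0,
  "peak_q_abs_r10": 2.4,
  "layer_t_453_fs075": 0.57,
  "np_t_453_fs10_r10": 0.946,
  "composite_jsc_r5_fs5_a_m2": 15.0,
  "k_term_delta_r75_fs5_033_a_m2": 3.0
 }
}
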