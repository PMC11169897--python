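a_radius_nm: 10.0
fill_fraction: 0.1
k_radius_nm: 25.0
k_gap_nm: 1.5
intensity_mW_mm2: 0.26
wavelength_nm: 453.0
layer_L_nm: 70.0
donor_W_nm: 14.0
acceptor_W_nm: 25.0
cell_area_um2: 10000.0
p_bare: 0.7
p_enhanced: 0.85
include_k_term: true
include_a_term: true
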