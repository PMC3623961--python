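method,e_hsa,e_bsa,ket_i_hsa_1e8,ket_i_bsa_1e8,ket_ii_hsa_1e8,ket_ii_bsa_1e8,ratio_i,ratio_ii
donor_quenching,0.42,0.45,2.15,1.673,4.0,3.36,1.28,1.19
acceptor_enhancement,0.50,0.55,2.37,2.33,4.21,3.81,1.02,1.105
phosphorescence,0.33,0.35,1.14,1.01,0.76,0.66,1.13,1.15
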