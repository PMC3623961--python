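trp,asa_free_A2,asa_complex_A2
BSA_Trp213,40.9,40.9
BSA_Trp134,15.4,15.4
HSA_Trp214,61.7,34.7
AP_Trp109,1.0,1.0
AP_Trp220,52.7,29.1
AP_Trp268,46.7,46.7
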