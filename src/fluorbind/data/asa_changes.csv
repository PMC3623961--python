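system,residue,delta_asa_A2
HSA-TC,Lys195,-40.43
HSA-TC,Trp214,-27.02
HSA-TC,Arg218,-37.41
HSA-TC,Glu294,-24.71
HSA-TC,Asn295,-20.28
HSA-TC,Lys444,-12.48
HSA-TC,Pro447,-17.38
HSA-TC,Cys448,-34.80
HSA-TC,Asp451,-30.12
HSA-TC,Tyr452,-18.98
HSA-TC,Val455,-11.22
BSA-TC,Arg194,-25.87
BSA-TC,Arg217,-39.58
BSA-TC,Glu291,-39.5
BSA-TC,Lys294,-29.52
BSA-TC,Val342,-18.45
BSA-TC,Lys439,-15.50
BSA-TC,Glu443,-14.16
BSA-TC,Asp450,-39.41
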