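trp,atom_pair,distance_A
BSA_Trp213,indole N to O attached with 3-C,10.00
BSA_Trp213,indole N to 5-C,10.74
BSA_Trp213,indole N to O attached with 10-C,12.13
BSA_Trp213,indole N to 12-C,9.63
BSA_Trp213,C1 to N attached with 4-C,13.76
BSA_Trp213,C1 to O attached with 6-C,14.20
BSA_Trp213,C1 to O attached with 11-C,11.30
BSA_Trp134,indole N to O attached with 3-C,30.42
BSA_Trp134,indole N to 5-C,26.46
BSA_Trp134,indole N to O attached with 10-C,20.84
BSA_Trp134,indole N to 12-C,25.67
BSA_Trp134,C1 to N attached with 4-C,30.99
BSA_Trp134,C1 to O attached with 6-C,27.68
BSA_Trp134,C1 to O attached with 11-C,24.72
HSA_Trp214,indole N to O attached with 3-C,6.25
HSA_Trp214,indole N to 5-C,8.6
HSA_Trp214,indole N to O attached with 10-C,12.21
HSA_Trp214,indole N to 12-C,8.01
HSA_Trp214,C1 to N attached with 4-C,10.15
HSA_Trp214,C1 to O attached with 6-C,12.20
HSA_Trp214,C1 to O attached with 11-C,10.50
AP_Trp109,indole N to O attached with 3-C,34.10
AP_Trp109,indole N to 5-C,30.67
AP_Trp109,indole N to O attached with 10-C,24.23
AP_Trp109,indole N to 12-C,28.66
AP_Trp109,C1 to N attached with 4-C,35.41
AP_Trp109,C1 to O attached with 6-C,31.10
AP_Trp109,C1 to O attached with 11-C,36.08
AP_Trp220,indole N to O attached with 3-C,6.52
AP_Trp220,indole N to 5-C,5.56
AP_Trp220,indole N to O attached with 10-C,7.57
AP_Trp220,indole N to 12-C,4.99
AP_Trp220,C1 to N attached with 4-C,9.00
AP_Trp220,C1 to O attached with 6-C,8.77
AP_Trp220,C1 to O attached with 11-C,8.56
AP_Trp268,indole N to O attached with 3-C,46.02
AP_Trp268,indole N to 5-C,44.8
AP_Trp268,indole N to O attached with 10-C,40.23
AP_Trp268,indole N to 12-C,42.07
AP_Trp268,C1 to N attached with 4-C,47.58
AP_Trp268,C1 to O attached with 6-C,44.63
AP_Trp268,C1 to O attached with 11-C,46.82
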