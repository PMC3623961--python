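system,protein,protein_conc_uM,lambda_max_nm,phi_x1e3,tau1_ns,f1,tau2_ns,f2,tau_av_ns,chi2
free_tc,none,0.0,515.0,0.26,1.60,0.051,0.30,0.949,0.37,1.17
bsa_2.5,BSA,2.5,506.4,0.46,1.90,0.074,0.46,0.926,0.57,0.99
bsa_5,BSA,5.0,502.8,0.68,1.99,0.136,0.63,0.864,0.81,1.10
bsa_10,BSA,10.0,501.4,0.95,2.11,0.200,0.76,0.800,1.03,1.01
bsa_15,BSA,15.0,500.6,1.23,2.52,0.215,0.99,0.785,1.32,1.00
bsa_20,BSA,20.0,500.2,1.28,2.60,0.236,1.02,0.764,1.39,1.15
bsa_25,BSA,25.0,498.4,1.55,2.62,0.228,1.11,0.772,1.4,0.99
hsa_2.5,HSA,2.5,496.0,0.28,1.95,0.030,0.49,0.970,0.54,1.06
hsa_5,HSA,5.0,492.8,0.31,2.18,0.041,0.51,0.958,0.58,1.18
hsa_10,HSA,10.0,490.0,0.44,2.72,0.077,0.69,0.923,0.85,1.01
hsa_15,HSA,15.0,489.8,0.48,3.04,0.099,0.87,0.901,1.07,0.99
hsa_20,HSA,20.0,489.8,0.58,3.05,0.110,0.95,0.890,1.18,1.2
hsa_25,HSA,25.0,489.8,0.70,3.22,0.112,0.96,0.888,1.20,1.1
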