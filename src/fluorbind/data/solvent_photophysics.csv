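system,lambda_em_nm,phi_x1e3,tau1_ns,f1,tau2_ns,f2,tau_av_ns,chi2,theta_c_ns,kr_1e6,knr_1e9,pi_star,alpha,beta,epsilon
DMSO,523.0,2.49,2.78,0.1824,1.53,0.8176,1.76,1.01,2.3,1.41,0.57,0.98,0.00,0.76,45.00
DMF,524.0,1.69,2.08,0.0981,0.91,0.9019,1.02,1.11,1.4,1.66,0.98,0.88,0.00,0.69,38.00
EG,530.0,1.44,1.93,0.2114,0.74,0.7886,0.99,0.99,3.4,1.46,1.01,0.88,0.90,0.52,37.00
EtOH,545.5,0.72,1.51,0.1378,0.58,0.8622,0.71,1.00,2.3,1.01,1.41,0.54,0.83,0.77,24.55
iPrOH,548.0,0.52,1.87,0.0213,0.49,0.9787,0.52,1.20,3.0,1.00,0.92,0.48,0.76,0.95,18.00
water,515.0,0.26,1.60,0.0506,0.30,0.9494,0.36,1.17,,0.71,2.73,1.09,1.17,0.18,80.0
HSA,490.0,0.70,3.22,0.112,0.96,0.888,1.20,1.10,6.0,0.59,0.83,,,,
BSA,498.0,1.55,2.62,0.228,1.11,0.772,1.45,0.99,5.0,1.07,0.69,,,,
AP,509.0,2.30,2.79,0.10,0.39,0.90,0.63,0.90,3.6,3.43,1.49,,,,
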