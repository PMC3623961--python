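system,method,k_assoc_M,dg_exp_kcal,dg_theory_kcal
HSA-TC,benesi_hildebrand,3.14e4,-6.17,-6.84
HSA-TC,anisotropy,4.49e4,,
HSA-TC,quenching,4.94e4,,
BSA-TC,benesi_hildebrand,4.72e4,-6.55,-7.38
BSA-TC,anisotropy,5.97e4,,
BSA-TC,quenching,6.2e4,,
AP-TC,benesi_hildebrand,6.8e6,-9.05,-8.49
AP-TC,anisotropy,1.9e6,,
AP-TC,quenching,3.9e6,,
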