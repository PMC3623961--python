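system,band_00_nm,fwhm_cm1
free_BSA,412.8,270
BSA-TC,413.4,305
free_HSA,410.0,332
HSA-TC,410.6,320
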