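step,peg_mw,protein_mg,activity_u,specific_activity,yield_pct,fold
crude,0,6879.45,796890.0,115.84,100.0,1.0
PEG-1500,1500,96.71,588673.75,6087.0,73.87,52.55
PEG-3000,3000,243.97,493823.36,2024.12,61.97,17.43
PEG-4500,4500,312.73,328834.03,1051.5,41.27,9.08
PEG-6000,6000,152.19,506459.74,3327.81,63.56,28.73
PEG-7500,7500,453.96,234979.12,517.61,29.49,4.47
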