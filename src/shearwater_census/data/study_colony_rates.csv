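colony_id,season,breeding_success,breeding_success_psd,occupancy,occupancy_psd,productivity,productivity_psd
CP,2006/7,0.76,0.06,0.61,0.07,0.46,0.06
CP,2007/8,0.71,0.04,0.70,0.05,0.49,0.05
CP,2008/9,0.69,0.03,0.67,0.04,0.46,0.04
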