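stratum,n_transects,area_m2,carcass_count
roadside,40,800,10
background,12,4116,2
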