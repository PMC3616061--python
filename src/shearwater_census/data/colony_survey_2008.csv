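colony_id,name,area_ha,n_transects,surveyed_area_m2,burrows_counted,printed_density_per_m2,printed_density_lo,printed_density_hi,printed_burrows,printed_burrows_lo,printed_burrows_hi,fully_counted
LMG,Little Muttonbird Ground,0.41,2,560,16,0.015,0.007,0.027,60,29,111,False
CP,Clear Place,7.73,4,2680,367,0.148,0.115,0.186,11407,8906,14350,False
MB,Middle Beach,5.88,4,2600,324,0.131,0.103,0.163,7680,6043,9566,False
NB,Ned's Beach,2.89,1,1240,149,0.125,0.083,0.180,3598,2392,5193,False
SP,Steven's Point,7.41,5,4000,204,0.061,0.047,0.077,4487,3470,5694,False
HB,Hunter Bay,0.41,0,,91,,,,91,91,91,True
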