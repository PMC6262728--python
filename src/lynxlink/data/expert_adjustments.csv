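feature,band_low_m,band_high_m,class_name,core_delta,travel_delta
developed,0,0,,8,4
developed,0,50,,6,2
developed,50,100,,3,1
developed,100,250,,1,0
highway,0,0,,7,3
highway,0,50,,4,1
highway,50,100,,2,0
highway,100,250,,0,0
cover,,,west_side_subboreal_forest,2,-1
cover,,,west_side_wet_forest,6,1
cover,,,agriculture,7,5
cover,,,water,6,4
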