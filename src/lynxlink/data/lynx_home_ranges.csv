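animal_id,area_km2,mean_habitat_value,sd_habitat_value
Male 339,674,5.0,2.7
Male 327,231,3.8,1.9
Male 311,127,5.9,2.1
Male 338,116,7.6,2.3
Male 346,98,7.4,1.8
Male 347,78,7.4,2.0
Male 309,75,8.0,1.8
Male 329,73,6.0,1.8
Male 336,36,,
Male 308,36,8.9,1.1
Male 348,19,7.9,1.9
Female 340,131,6.1,1.9
Female 330,67,6.8,1.5
Female 349,61,8.6,1.4
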