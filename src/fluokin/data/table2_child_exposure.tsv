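age_years	body_weight_kg	height_cm	toothpaste_ug_kg_day	diet_ug_kg_day	soil_ug_kg_day	air_ug_kg_day	water_l_day
4	16	103	40	21	1.19	0.01	0.442
8	25	127	30	17.5	0.21	0.01	0.56
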