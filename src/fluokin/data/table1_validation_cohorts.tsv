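age_years	n_children	intake_diet_mg_day	intake_toothpaste_mg_day	intake_water_mg_day	intake_supplement_mg_day	measured_auf24_mg_day	country
4	31	0.560	0.706	0.042	0	0.3682	Venezuela
4	20	0.533	0.254	0.231	0	0.358	Chile
5	61	0.151	0.608	0.407	0	0.3705	UK
5	11	0.092	0.274	0.111	0.455	0.476	Germany
7	21	0.187	0.606	0.154	0	0.297	UK
7	12	0.229	1.130	0.349	0	0.393	UK
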