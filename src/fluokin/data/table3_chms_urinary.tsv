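region	age_group_median	statistic	urinary_concentration_mg_l
Ontario	4	geometric_mean	0.83
Ontario	8	geometric_mean	0.67
Quebec	4	geometric_mean	0.39
Quebec	8	geometric_mean	0.34
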