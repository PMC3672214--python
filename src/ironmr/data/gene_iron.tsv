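study_id	rsid	gene	effect_allele	other_allele	eaf	scale	beta	se	or	ci_low	ci_high	p	n	n_case	n_control	design	pop_strat_adjusted	population
GIS-consortium-pooled	rs1800562	HFE	A	G	0.07	sd-units	0.37	0.020408538277		0.33	0.41	4e-77	21567			gwa	true	Europe/Australia
GIS-consortium-pooled	rs1799945	HFE	G	C	0.15	sd-units	0.19	0.0102042691385		0.17	0.21	1.7e-42	21567			gwa	true	Europe/Australia
GIS-consortium-pooled	rs855791	TMPRSS6	G	A	0.4	sd-units	0.19	0.0102042691385		0.17	0.21	4.3e-77	21567			gwa	true	Europe/Australia
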