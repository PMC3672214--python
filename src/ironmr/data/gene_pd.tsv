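study_id	rsid	gene	effect_allele	other_allele	eaf	scale	beta	se	or	ci_low	ci_high	p	n	n_case	n_control	design	pop_strat_adjusted	population
PD-meta-pooled	rs1800562	HFE	A	G	0.07	log-odds			0.97	0.92	1.02	0.281	109701	20809	88892	gwa	true	Europe/North America
PD-meta-pooled	rs1799945	HFE	G	C	0.15	log-odds			0.99	0.96	1.03	0.715	109701	20809	88892	gwa	true	Europe/North America
PD-meta-pooled	rs855791	TMPRSS6	G	A	0.4	log-odds			0.97	0.94	0.99	0.034	109701	20809	88892	gwa	true	Europe/North America
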