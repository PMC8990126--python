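patient_ids	gene	transcript	hgvs_c	hgvs_p	consequence	subclass	followup_studies	segregation	protein_model	functional	final_class	outcome_note
38	AFG3L2	NM_006796.2	c.2143C>T	p.L715F	missense	high	PM	unavailable	predicts_lb	unavailable	VUS	PM predicted LB
28	CACNA1A	NM_023035.2	c.5669T>A	p.V1890D	missense	high	PM	unavailable	predicts_lp	unavailable	VUS	PM predicted LP
30	CACNA1A	NM_023035.2	c.2357G>C	p.R786P	missense	high	SS	supports_lp	unavailable	unavailable	LP	SS indicates LP
31	CACNA1A	NM_023035.2	c.1586T>C	p.L529P	missense	high	PM	unavailable	predicts_lp	unavailable	VUS	PM predicted LP
32	CACNA1A	NM_023035.2	c.5157T>A		synonymous	splice	FT	unavailable	unavailable	indicates_lb	VUS	FT indicates LB
43	CACNA1G	NM_018896.4	c.3792G>T		synonymous	splice	FT	unavailable	unavailable	indicates_lp	LP	FT indicates LP
40	DAB1	NM_021080.4	c.209G>A	p.G70D	missense	semi_high	PM	unavailable	predicts_lb	unavailable	VUS	PM predicted LB
27	FAT1	NM_005245.3	c.8991G>A		synonymous	splice	FT	unavailable	unavailable	indicates_lb	VUS	FT indicates LB
39	NOP56	NM_006392.3	c.909G>A		synonymous	splice	FT	unavailable	unavailable	indicates_lp	LP	FT indicates LP
4	PDYN	NM_024411.4	c.635G>A	p.R212Q	missense	semi_high	PM	unavailable	predicts_lp	unavailable	VUS	PM predicted LP; co-occurs with a known LP variant in CACNA1A
37	PRKCG	NM_002739.3	c.715C>T	p.R239W	missense	high	PM,SS,FT	supports_lp	predicts_lp	indicates_lp	LP	PM predicted LP; SS and FT indicate LP
26	SPTBN2	NM_006946.3	c.1522A>C	p.N508H	missense	semi_high	PM	unavailable	predicts_lb	unavailable	VUS	PM predicted LB
9	TGM6	NM_198994.2	c.1171G>A	p.V391M	missense	semi_high	PM,FT	unavailable	predicts_lb	indicates_lb	VUS	PM predicted LB; FT indicates LB; co-occurs with a known P variant in KCNC3
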