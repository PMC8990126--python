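patient_ids	gene	sca_type	transcript	hgvs_c	hgvs_p	consequence	pathogenicity_score	gnomad_ac	gnomad_an	splice_consensus	subclass	excluded_reclass	exclusion_reason
23	ATXN2	SCA2	NM_002973.3	c.974T>C	p.M325T	missense	3	1	245828	false	semi_high	true	patient diagnosed with autosomal recessive spinocerebellar ataxia-17
24	SPTBN2	SCA5	NM_006946.3	c.7109G>A	p.R2370H	missense	3.2	24	245754	false	semi_high	false
25	SPTBN2	SCA5	NM_006946.3	c.6169G>T	p.A2057S	missense	4			false	high	false
25	KIF26B		NM_018012.4	c.2605G>A	p.G869R	missense	4.1	12	276886	false	semi_high	false
26	SPTBN2	SCA5	NM_006946.3	c.1522A>C	p.N508H	missense	5	17	272418	false	semi_high	false
27	CACNA1A	SCA6	NM_023035.2	c.6418C>T	p.R2140C	missense	3.1	6	96904	false	semi_high	false
27	FAT1		NM_005245.3	c.8991G>A		synonymous				true	splice	false
28	CACNA1A	SCA6	NM_023035.2	c.5669T>A	p.V1890D	missense	3.1			false	high	false
4	PDYN	SCA23	NM_024411.4	c.635G>A	p.R212Q	missense	4.1	26	282806	false	semi_high	false
29	CACNA1A	SCA6	NM_023035.2	c.3161T>C	p.I1054T	missense	3			false	high	false
30	CACNA1A	SCA6	NM_023035.2	c.2357G>C	p.R786P	missense	3.1			false	high	false
31	CACNA1A	SCA6	NM_023035.2	c.1586T>C	p.L529P	missense	3			false	high	false
32	CACNA1A	SCA6	NM_023035.2	c.5157T>A		synonymous				true	splice	false
33	ATXN7	SCA7	NM_000333.3	c.2528C>T	p.S843L	missense	3.1	9	246040	false	semi_high	false
34	ATXN10	SCA10	NM_013236.3	c.404G>T	p.G135V	missense	3.1	50	277128	false	semi_high	false
35	KCNC3	SCA13	NM_004977.2	c.1130T>C	p.L377P	missense	4.1			false	high	false
36	KCNC3	SCA13	NM_004977.2	c.1876G>T	p.G626W	missense	4	2	131410	false	semi_high	false
37	PRKCG	SCA14	NM_002739.3	c.715C>T	p.R239W	missense	3.2			false	high	false
38	AFG3L2	SCA28	NM_006796.2	c.2143C>T	p.L715F	missense	4			false	high	false
38	TRPC3	SCA41	NM_001130698.1	c.949G>A	p.E317K	missense	3.2			false	high	false
9	TGM6	SCA35	NM_198994.2	c.1171G>A	p.V391M	missense	4	206	277194	false	semi_high	false
39	NOP56	SCA36	NM_006392.3	c.909G>A		synonymous				true	splice	false
40	DAB1	SCA37	NM_021080.4	c.209G>A	p.G70D	missense	3	1	223040	false	semi_high	false
41	ELOVL5	SCA38	NM_001301856.1	c.490G>A	p.G164S	missense	3			false	high	false
42	CCDC88C	SCA40	NM_001080414.3	c.6026C>T	p.P2009L	missense	4	168	270454	false	semi_high	false
43	CACNA1G	SCA42	NM_018896.4	c.3792G>T		synonymous				true	splice	false
44	GRM1	SCA44	NM_001278064.1	c.3236C>T	p.P1079L	missense	3	1	243296	false	semi_high	false
45	FAT2	SCA45	NM_001447.2	c.12899T>C	p.M4300T	missense	3	2	30892	false	semi_high	true	patient diagnosed with multiple system atrophy
46,47	FAT2	SCA45	NM_001447.2	c.12464C>G	p.S4155C	missense	3.2	231	274944	false	semi_high	true	patient diagnosed with epilepsy
48	EP300		NM_001429.3	c.214C>A	p.Q72K	missense	3.2	7	246266	false	semi_high	false
49	FAT1		NM_005245.3	c.8041C>T	p.P2681S	missense	5	11	277060	false	semi_high	false
50	FAT1		NM_005245.3	c.7130C>T	p.T2377M	missense	3	186	277024	false	semi_high	false
51	FAT1		NM_005245.3	c.6808G>A	p.D2270N	missense	4	12	276942	false	semi_high	false
52	FAT1		NM_005245.3	c.5762G>T	p.G1921V	missense	5.1			false	high	false
53	FAT1		NM_005245.3	c.1940C>T	p.A647V	missense	5	23	277126	false	semi_high	false
54	FAT1		NM_005245.3	c.544G>A	p.G182R	missense	5.1	8	277210	false	semi_high	false
55	KIF26B		NM_018012.4	c.1340G>A	p.G447E	missense	4			false	high	false
56	KIF26B		NM_018012.4	c.2605G>A	p.G869R	missense	4.1	12	276886	false	semi_high	false
57	KIF26B		NM_018012.4	c.2023G>C	p.D675H	missense	4	10	245992	false	semi_high	false
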