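patient_ids	gene	sca_type	transcript	hgvs_c	hgvs_p	consequence	tier	reported
1	CACNA1A	SCA6	NM_023035.2	c.835C>T	p.R279C	missense	P	literature
2	CACNA1A	SCA6	NM_023035.2	c.1748G>A	p.R583Q	missense	P	literature
3	CACNA1A	SCA6	NM_023035.2	c.3426delG	p.T1143Pfs*47	frameshift	P	novel
4	CACNA1A	SCA6	NM_023035.2	c.4997G>A	p.R1666H	missense	LP	literature
5	TTBK2	SCA11	NM_173500.3	c.3466C>T	p.R1156*	nonsense	LP	novel
6,7	KCNC3	SCA13	NM_004977.2	c.1771A>G	p.S591G	missense	LP	literature
8	KCNC3	SCA13	NM_004977.2	c.1268G>A	p.R423H	missense	P	literature
9	KCNC3	SCA13	NM_004977.2	c.1259G>A	p.R420H	missense	P	literature
10	PRKCG	SCA14	NM_001316329.1	c.107A>G	p.H36R	missense	P	literature
11	KCND3	SCA19/22	NM_004980.4	c.1054A>C	p.T352P	missense	P	literature
12	KCND3	SCA19/22	NM_004980.4	c.1169G>A	p.S390N	missense	P	literature
13	KCND3	SCA19/22	NM_004980.4	c.1291C>T	p.R431C	missense	LP	literature
14	PDYN	SCA23	NM_001190892.1	c.632T>C	p.L211S	missense	P	literature
15	AFG3L2	SCA28	NM_006796.2	c.1861C>G	p.L621V	missense	P	literature
16	TGM6	SCA35	NM_198994.2	c.691C>T	p.R231*	nonsense	P	novel
17	TGM6	SCA35	NM_198994.2	c.1429_1430insTCTCT	p.G477Vfs*28	frameshift	P	novel
18	MME	SCA43	NM_000902.3	c.1095-2A>C		splice_canonical	LP	novel
19	GRM1	SCA44	NM_001278064.1	c.2375A>G	p.Y792C	missense	P	literature
20	FAT2	SCA45	NM_001447.2	c.10758G>C	p.K3586N	missense	P	literature
21,22	KIF26B		NM_018012.3	c.5710G>A	p.D1904N	missense	P	literature
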