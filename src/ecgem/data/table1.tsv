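reaction_id	gene	ec	equation	kcat_per_s	mw_kda	abundance_mmol_gdw	abundance_source	kcat_organism
PGI	pgi	5.3.1.9	g6p -> f6p	126		1.55e-05	proteomics	E. coli
TPI	tpiA	4.1.1.31	dhap -> g3p	150		1.28e-05	proteomics	E. coli
GAPD_NAD	gapA	1.2.1.12	g3p + nad + pi -> 13dpg + h + nadh	70		5.77e-05	proteomics	B. subtilis
PGK	pgk	2.7.2.3	13dpg + adp -> 3pg + atp	329		3.60e-05	proteomics	E. coli
PGM	pgm	5.4.2.12	3pg -> 2pg	765.9		8.85e-06	proteomics	B. subtilis
ENO	eno	4.2.1.11	2pg -> h2o + pep	130.4		3.17e-05	proteomics	B. subtilis
G6PDH	zwf	1.1.1.49	g6p + nadp -> 6pgl + h + nadph	174		8.05e-06	proteomics	E. coli
CS	citZ	2.3.3.16	accoa + h2o + oaa -> cit + coa + h	49		2.51e-05	proteomics	B. subtilis
ICDHy	icd	1.1.1.42	icit + nadp -> akg + co2 + nadph	82		1.10e-04	proteomics	B. subtilis
FUM	citG	4.2.1.2	fum + h2o -> mal-l	283.3		7.29e-06	proteomics	E. coli
MDH	mdh	1.1.1.37	mal-l + nad -> h + nadh + oaa	177.1		1.06e-04	proteomics	B. subtilis
PTAr	pta	2.3.1.8	accoa + pi -> actp + coa	651.6		8.49e-06	proteomics	B. subtilis
LDH_L	ldh	1.1.1.27	lac-l + nad -> h + nadh + pyr	6416.6		3.60e-06	proteomics	B. subtilis
PGCDr	serA	1.1.1.95	3pg + nad -> 3php + h + nadh	14.56		1.90e-05	proteomics	B. subtilis
OXADC	oxdC	4.1.1.2	h + oxa -> co2 + for	59		6.21e-07	proteomics	B. subtilis
MICITL	yqiQ	4.1.3.30	micit -> pyr + succ	19		6.80e-08	detection_floor	E. coli
OXGDC	menD	4.1.1.71	akg + h -> co2 + sucsal	0.2		6.80e-08	detection_floor	B. subtilis
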