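gene	cys	protein	localization	std_D0	std_D1	std_D2	std_D3	std_D4	cr_D0	cr_D1	cr_D2	cr_D3	cr_D4	cr_D5	cr_D7	peroxide_sensitive	general_pattern
CCT4	399	T-complex protein 1 subunit delta	C	12	24	58	87	86	12	14	13	11	39	72	82	0	0
ARO2	221	Chorismate synthase	C	13	13	31	71	74								1	0
CDC48	115	Cell division control protein 48	ER;C	12	29	55	75	93	13	15	14	28	62	68	90	0	0
CCT8	336	T-complex protein 1 subunit theta	C	47	40	77	76	89								0	0
TRR	142;145	Thioredoxin reductase	C;M	33	33	65	77	82	34	39	42	44	73	80	86	0	0
UBC4	108	Ubiquitin-conjugating enzyme E2 4	N	19	23	48	70	81	20	15	22	24	49	73	88	0	0
YCR090C	124	UPF0587 protein	C;N	34	39	67	76	88								0	0
LYS2	614	L-aminoadipate-semialdehyde DH	C	15	22	49	79	86	14	11	12	48	56	74	81	0	0
YDJ1	185;188	Homologue of DnaJ	C	46	46	82	89	75	45	44	51	70	73	83	88	1	0
MES1	353	Methionyl-tRNA synthetase	C	23	34	64	86	82	20	21	31	61	78	80	98	0	0
OLA1	43	Uncharacterized GTP-binding protein	C	17	12	46	91	83	20	10	22	29	53	78	88	0	0
PAA1	51;55	Polyamine N-acetyltransferase 1	C	26	36	53	48	61	18	15	25	52	61	71	83	0	0
PRB1	36	Cerevisin	V	18	23	57	91	94	12	14	26	23	77	80	88	0	0
PUT2	162	delta-1-pyrroline-5-carboxylate DH	M	12	10	35	60	66								0	0
RPL10	49	60S protein L10	C	15	15	31	73	89	21	17	28	23	59	80	90	0	0
RPL42B	74	60S protein L42	C	15	22	49	86	86	15	19	25	49	54	77	93	1	0
RPS11B	58	40S protein S11	C	18	17	37	77	81	14	17	27	25	36	83	86	0	0
RPS22B	72	40S protein S22-B	C	13	9	34	62	72	32	29	36	32	41	72	79	0	0
SES1	413;414	Seryl-tRNA synthetase	C	22	23	55	66	79	20	19	17	43	65	71	81	1	0
HEM1	386	5-aminolevulinate synthase	M	13	21	58	77	88								0	0
IDP1	398	Isocitrate dehydrogenase 1	M	18	19	41	61	85	16	18	32	25	49	81	80	0	0
KGD1	983	2-oxoglutarate dehydrogenase E1	M	25	21	49	57	84	18	18	19	16	57	54	70	0	0
FAS2	917	Fatty acid synthase subunit alpha	C;M	22	16	30	62	86	14	8	15	59	81	87	72	0	0
ERG13	300	Hydroxymethylglutaryl-CoA synthase	ER	17	38	47	80	91	16	18	30	44	55	70	84	0	0
FUS2	371	Nuclear fusion protein FUS2	N	18	33	57	68	80	9	18	12	20	31	64	91	0	0
LAP4	202	Vacuolar aminopeptidase 1	V	19	38	45	83	86	25	35	27	22	39	61	81	0	0
PYC2	218	Pyruvate carboxylase 2	C	11	28	46	81	93	13	11	22	47	66	77	81	0	0
TEF1	409	Elongation factor 1-alpha	C	13	38	40	62	70	18	30	17	26	36	57	68	1	0
GapDH	150;154	Glyceraldehyde-3-P Dehydrogenase	C	26	22	28	70	81	24	22	21	26	28	72	87	0	1
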