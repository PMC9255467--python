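gene	betweenness	closeness	degree	regulation
PHLDA1	213.0074	0.005618	22	up
CTSC	149.7385	0.005495	18	down
HADH	208.3918	0.00578	18	down
RPL14	139.3092	0.005464	17	down
ZBTB16	127.1864	0.005405	14	up
SOD3	198.8821	0.005714	21	up
SNAP25	380.1873	0.005814	30	down
SLC2A2	438.8331	0.005747	26	down
ISLR	465.6411	0.005952	27	up
SCN1B	175.7841	0.005376	14	up
MMP9	196.9649	0.005682	22	up
ENPP2	230.6537	0.005618	17	down
TAP1	189.4171	0.005376	40	predicted
MCL1	320.3027	0.005917	27	up
DPEP1	133.0483	0.005208	15	predicted
CNTNAP2	761.7546	0.006494	39	up
STMN2	200.277	0.005618	18	down
PPP1R1A	219.8601	0.005587	18	down
ZNF423	406.5439	0.006061	21	up
CNTFR	200.657	0.005319	16	up
TNFAIP6	162.3969	0.005208	14	up
PPP1R15A	119.5084	0.005155	13	predicted
XYLT1	194.4998	0.00565	18	up
ZMIZ1	392.1699	0.005682	26	predicted
RASL11B	168.9444	0.005376	13	up
ARG1	124.961	0.005263	18	predicted
UGT2B7	247.0102	0.005682	19	down
CD226	222.4953	0.005495	17	predicted
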