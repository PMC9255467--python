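source	gene	regulation
REM	XYLT1	up
REM	ISLR	up
REM	CRTAC1	up
REM	ERAP2	up
REM	PCOLCE2	up
REM	VNN2	up
REM	U2AF2	up
REM	NPTX2	up
REM	MMP9	up
REM	LOC100008589	up
REM	DYRK3	up
REM	LOC649456	up
REM	BCL3	up
REM	ZNF423	up
REM	SOD3	up
REM	CNTFR	up
REM	ZNF75	up
REM	RNF19B	up
REM	TNFAIP6	up
REM	TAPBP	up
REM	PHACTR3	up
REM	PHLDA1	up
REM	ALDOB	up
REM	PRIMA1	up
REM	PVRL2	up
REM	CNTNAP2	up
REM	RASL11B	up
REM	POMZP3	up
REM	ELFN1	up
REM	ESPNL	up
REM	PI3	up
REM	SCN1B	up
REM	EGR2	up
REM	MGRN1	up
REM	SLC9A3R2	up
REM	LOC650885	down
REM	UGT2B7	down
REM	C19ORF33	down
REM	HLA-DRB4	down
REM	OR8B12	down
REM	HLA-DRB5	down
REM	IFNA7	down
REM	LOC389286	down
REM	FUT11	down
REM	APOL4	down
REM	LOC731682	down
REM	KIAA1984	down
REM	POPDC3	down
REM	TAP2	down
VC	LOC644422	up
VC	MCL1	up
VC	CTSC	down
VC	DYRK2	down
VC	MCOLN3	down
VC	TMEM37	down
VC	API5	down
VC	ARG2	down
VC	C14ORF132	down
VC	COG2	down
VC	DHRS2	down
VC	ENPP2	down
VC	ENTPD3	down
VC	HADH	down
VC	KIAA1279	down
VC	LARP4	down
VC	MARK1	down
VC	MTRR	down
VC	NAALAD2	down
VC	PAAF1	down
VC	PPM1K	down
VC	PPP1R1A	down
VC	RPL14	down
VC	SLC2A2	down
VC	SNAP25	down
VC	STMN2	down
VC	NMNAT2	down
CA	PCOLCE2	up
CA	ERAP2	up
CA	EGR2	up
CA	ZBTB16	up
CA	SLC2A2	down
CA	ARG2	down
CA	ASCL2	down
CA	IAPP	down
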