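mouse_gene	zebrafish_gene	mouse_phase	zebrafish_phase
Arntl	arntl1b	22.37	12.79
Arntl	arntl1a	22.37	13.42
Clock	clock	23.35	15.08
Clock	clock3	23.35	15.08
Cry1	cry-dash	17.98	3.58
Cry1	cry1a	17.98	Not present
Cry1	cry2a	17.98	13.33
Cry1	cry4	17.98	14.29
Cry1	cry1b	17.98	6.46
Cry1	cry2b	17.98	14.08
Cry1	cry5	17.98	4.00
Cry2	cry-dash	12.23	3.58
Cry2	cry3	12.23	2.17
Cry2	cry4	12.23	14.29
Cry2	cry5	12.23	4.00
Dbp	dbpb	9.18	23.25
Dbp	dbpa	9.18	Not present
Hlf	hlfb	13.21	14.25
Hlf	hlfa	13.21	Not oscillating
Nfil3	nfil3-2	20.33	Not oscillating
Nfil3	nfil3-6	20.33	5.92
Nfil3	nfil3-4	20.33	Not oscillating
Nfil3	nfil3	20.33	14.42
Nr1d1	nr1d4b	6.19	19.75
Nr1d1	nr1d1	6.19	23.75
Nr1d1	nr1d4a	6.19	19.83
Nr1d2	nr1d4b	9.60	19.75
Nr1d2	nr1d2b	9.60	Not present
Nr1d2	nr1d4a	9.60	19.83
Nr1d2	nr1d2a	9.60	Not oscillating
Per1	per1b	11.44	3.33
Per1	per1a	11.44	1.04
Per2	per2	13.22	7.50
Per3	per3	11.44	4.17
Rora	roraa	11.65	Not oscillating
Rora	rorab	11.65	7.50
Rorb	rorb	9.67	Not oscillating
Rorc	rorca	18.27	10.75
Rorc	rorcb	18.27	12.42
Tef	tefa	11.48	3.42
Tef	tefb	11.48	1.92
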