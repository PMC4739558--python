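species_pair	introduced	source	markers	n_present	n_no_parentals	n_absent
RT x PCT	RT	Busack and Gall	10	2	0	0
RT x CCT		Campton and Utter	4	8	1	0
YCT x WCT	YCT	Gyllensten et al.	11	2	2	0
YCT x WCT	YCT,WCT	Marnell et al.	6	3	1	0
RT x LCT	RT	Bartley and Gall	5	1	0	3
YCT x WCT	YCT	Forbes and Allendorf	12	3	3	0
RT x CCT		Young et al.	23	5	0	11
RT x CCT		Docker et al.	4	6	0	4
RT x CCT		Ostberg et al.	22	7	0	0
RT x LCT	RT	Peacock and Kirchoff	10	3	1	1
RT x WCT	RT	Rubidge and Taylor	4	18	0	5
RT x CCT		Baumsteiger et al.	7	3	0	0
RT x WCT	RT	Ostberg and Rodriguez	4	14	0	4
RT x WCT		Kozfkay et al.	3	14	0	3
RT x CCT		Williams et al.	4	8	0	5
RT x WCT	RT	Boyer et al.	7	17	1	14
RT x YCT	RT	Gunnell et al.	7	16	0	12
RT x CRCT	RT	Metcalf et al.	7	2	0	2
RT x WCT	RT	Bennett and Kershner	4	11	0	3
RT x WCT	RT	Muhlfeld et al.	16	1	0	0
RT x CCT		Heath et al.	7	29	0	6
RT x WCT	RT	Rasmussen et al.	3	16	0	7
RT x YCT	RT	Kovach et al.	14	10	0	0
WCT x RT	WCT	Neville and Dunham	7	14	0	27
RT x WCT	RT	Ostberg and Chase	4	6	0	2
RT x CCT		Buehrens et al.	4	1	0	0
RT x WCT		Loxterman et al.	6	25	0	7
RT x WCT	RT	Kovach et al. (b)	8	2	0	0
RT x YCT x LCT	RT,YCT	Pritchard et al.	46	7	4	26
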