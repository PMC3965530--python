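gene	chrom	pos	ref_base	alt_base	effect	cds_change	protein_change	sample_id
CDH1	16	68835696	T	C	NON_SYNONYMOUS	aTc/aCc	p.I96T	X19
CDKN2A	9	21971012	C	A	NON_SYNONYMOUS	gGa/gTa	p.G130V	X1
CEBPA	19	33792354	G	C	NON_SYNONYMOUS	Cgc/Ggc	p.R323G	X15
FES	15	91428715	C	T	NON_SYNONYMOUS	tCa/tTa	p.S96L	X33
FGFR3	4	1807891	G	T	NON_SYNONYMOUS	aaG/aaT	p.K652N	X21
FGFR3	4	1803568	C	G	NON_SYNONYMOUS	tCc/tGc	p.S249C	X20
FLT3	13	28608286	G	C	NON_SYNONYMOUS	ttC/ttG	p.F590L	X25
MPL	1	43814963	C	G	NON_SYNONYMOUS	Cta/Gta	p.L500V	X35
NOTCH1	9	139401189	C	A	STOP_GAINED	Gag/Tag	p.E1294*	X35
NOTCH1	9	139418406	G	A	STOP_GAINED	Cga/Tga	p.R56*	X28
NOTCH1	9	139396309	C	T	STOP_GAINED	tgG/tgA	p.W1843*	X11
PIK3CA	3	178936091	G	A	NON_SYNONYMOUS	Gag/Aag	p.E545K	X25
PIK3R1	5	67588148	G	A	NON_SYNONYMOUS	atG/atA	p.M26I	X13
TP53	17	7578526	C	A	NON_SYNONYMOUS	tGc/tTc	p.C135F	X1
TP53	17	7578406	C	T	NON_SYNONYMOUS	cGc/cAc	p.R175H	X27
TP53	17	7578403	C	T	NON_SYNONYMOUS	tGc/tAc	p.C176Y	X4
TP53	17	7578394	T	C	NON_SYNONYMOUS	cAt/cGt	p.H179R	X33
TP53	17	7578190	T	C	NON_SYNONYMOUS	tAt/tGt	p.Y220C	X5
TP53	17	7577581	A	T	NON_SYNONYMOUS	Tac/Aac	p.Y234N	X16
TP53	17	7577580	T	G	NON_SYNONYMOUS	tAc/tCc	p.Y234S	X12
TP53	17	7577559	G	A	NON_SYNONYMOUS	tCc/tTc	p.S241F	X16
TP53	17	7577538	C	T	NON_SYNONYMOUS	cGg/cAg	p.R248Q	X34
TP53	17	7577121	G	A	NON_SYNONYMOUS	Cgt/Tgt	p.R273C	X28
TP53	17	7577094	G	A	NON_SYNONYMOUS	Cgg/Tgg	p.R282W	X23
TP53	17	7576897	G	A	STOP_GAINED	Cag/Tag	p.Q317*	X35
TP53	17	7574003	G	A	STOP_GAINED	Cga/Tga	p.R342*	X27
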