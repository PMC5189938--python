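# Published per-hotspot lavage mutation counts for the 12-gene panel
# (hotspot-table input data). expand_change is a representative
# protein change for reconstructing a mutation list at these counts.
gene	hotspot_label	expand_change	lavage_count	tcga_count	novel
PIK3CA	H1047R	H1047R	8	20	0
PIK3CA	E545K/A	E545K	4	14	0
PIK3CA	E542K/A	E542K	4	13	0
PIK3CA	R88Q	R88Q	2	11	0
PIK3CA	Q546K	Q546K	1	11	0
PIK3CA	R93W/Q	R93W	3	6	0
PIK3CA	M1043V	M1043V	1	6	0
PIK3CA	C420R	C420R	1	4	0
PIK3CA	G106V	G106V	2	1	0
PIK3CA	V344G	V344G	2	3	0
PIK3CA	N345I/T	N345I	2	5	0
PIK3CA	K111R	K111R	1	4	0
PIK3CA	E453K	E453K	1	1	0
PIK3CA	E81K	E81K	1	1	0
KRAS	G12D,V	G12D	21	36	0
KRAS	G13C	G13C	1	9	0
KRAS	Q61L	Q61L	1	3	0
PTEN	R130G/Q/*	R130G	7	57	0
PTEN	Y16*	Y16*	1	3	0
PTEN	A72fs	A72fs	1	1	0
PTEN	G132D	G132D	1	1	0
PTEN	I33S	I33S	1	1	0
PTEN	I67R	I67R	1	1	0
PTEN	D92E	D92E	1	2	0
PTEN	G165E	G165E	1	3	0
PTEN	R173C	R173C	1	2	0
PTEN	I32del	I32del	1	0	1
PTEN	W111*	W111*	1	0	1
PTEN	Y176del	Y176del	1	0	1
PTEN	L318fs	L318fs	1	0	1
PTEN	T321fs	T321fs	1	0	1
PTEN	F337fs	F337fs	1	0	1
PTEN	K342fs	K342fs	1	0	1
PTEN	P95L	P95L	1	0	1
PTEN	K128Q	K128Q	1	0	1
PTEN	C211Y	C211Y	1	0	1
PIK3R1	D578H/A	D578H	2	5	0
PIK3R1	T576delT	T576delT	1	2	0
PIK3R1	Y580fs	Y580fs	1	1	0
PIK3R1	Y580D	Y580D	1	3	0
PIK3R1	R514C	R514C	1	1	0
PIK3R1	R461*	R461*	1	2	0
PIK3R1	Y463_L466del	Y463_L466del	1	0	1
PIK3R1	E558fs	E558fs	1	0	1
PIK3R1	L570fs	L570fs	1	0	1
PIK3R1	D464del	D464del	1	0	1
ARID1A	R1989*	R1989*	1	9	0
ARID1A	R1722*	R1722*	2	2	0
ARID1A	R1446*	R1446*	1	1	0
ARID1A	E1444*	E1444*	1	0	1
FGFR2	S252W	S252W	4	9	0
FBXW7	R505C/G	R505C	3	6	0
FBXW7	R479Q	R479Q	3	1	0
FBXW7	R465C	R465C	1	7	0
FBXW7	R441L	R441L	1	1	0
TP53	R273H	R273H	1	9	0
TP53	S241F	S241F	1	3	0
TP53	S166fs	S166fs	1	0	1
TP53	Q165fs	Q165fs	1	0	1
CTNNB1	S37F	S37F	1	20	0
CTNNB1	D32Y/A	D32Y	2	12	0
CTNNB1	S45F	S45F	2	3	0
CTNNB1	T41A	T41A	1	5	0
RB1	R445*	R445*	1	0	1
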