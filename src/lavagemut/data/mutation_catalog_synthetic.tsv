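# Synthetic stand-in cohort-scale unique-mutation catalogue (no full mutation
# list is publicly deposited for this assay). Drivers are the unique published
# hotspot-table entries; potential drivers and passengers are constructed to
# match the published 75/23/28 partition and its 11/2/10 sub-annotation.
# expected_label is the generator's truth label.
gene	protein_change	expected_label
PIK3CA	H1047R	driver
PIK3CA	E545K	driver
PIK3CA	E545A	driver
PIK3CA	E542K	driver
PIK3CA	E542A	driver
PIK3CA	R88Q	driver
PIK3CA	Q546K	driver
PIK3CA	R93W	driver
PIK3CA	R93Q	driver
PIK3CA	M1043V	driver
PIK3CA	C420R	driver
PIK3CA	G106V	driver
PIK3CA	V344G	driver
PIK3CA	N345I	driver
PIK3CA	N345T	driver
PIK3CA	K111R	driver
PIK3CA	E453K	driver
PIK3CA	E81K	driver
KRAS	G12D	driver
KRAS	G12V	driver
KRAS	G13C	driver
KRAS	Q61L	driver
PTEN	R130G	driver
PTEN	R130Q	driver
PTEN	R130*	driver
PTEN	Y16*	driver
PTEN	A72fs	driver
PTEN	G132D	driver
PTEN	I33S	driver
PTEN	I67R	driver
PTEN	D92E	driver
PTEN	G165E	driver
PTEN	R173C	driver
PTEN	I32del	driver
PTEN	W111*	driver
PTEN	Y176del	driver
PTEN	L318fs	driver
PTEN	T321fs	driver
PTEN	F337fs	driver
PTEN	K342fs	driver
PTEN	P95L	driver
PTEN	K128Q	driver
PTEN	C211Y	driver
PIK3R1	D578H	driver
PIK3R1	D578A	driver
PIK3R1	T576delT	driver
PIK3R1	Y580fs	driver
PIK3R1	Y580D	driver
PIK3R1	R514C	driver
PIK3R1	R461*	driver
PIK3R1	Y463_L466del	driver
PIK3R1	E558fs	driver
PIK3R1	L570fs	driver
PIK3R1	D464del	driver
ARID1A	R1989*	driver
ARID1A	R1722*	driver
ARID1A	R1446*	driver
ARID1A	E1444*	driver
FGFR2	S252W	driver
FBXW7	R505C	driver
FBXW7	R505G	driver
FBXW7	R479Q	driver
FBXW7	R465C	driver
FBXW7	R441L	driver
TP53	R273H	driver
TP53	S241F	driver
TP53	S166fs	driver
TP53	Q165fs	driver
CTNNB1	S37F	driver
CTNNB1	D32Y	driver
CTNNB1	D32A	driver
CTNNB1	S45F	driver
CTNNB1	T41A	driver
RB1	R445*	driver
KRAS	G12S	driver
TP53	C176F	potential_driver
PIK3CA	E726K	potential_driver
PIK3CA	R108H	potential_driver
PTEN	F341V	potential_driver
KRAS	A146T	potential_driver
CTNNB1	G34R	potential_driver
FBXW7	S582L	potential_driver
FGFR2	C382R	potential_driver
ATM	R337C	potential_driver
APC	E1317Q	potential_driver
PIK3R1	K567E	potential_driver
PTEN	Q171E	potential_driver
ARID1A	M1022T	potential_driver
PIK3CA	L866F	potential_driver
PTEN	D107Y	potential_driver
TP53	P151T	potential_driver
CTNNB1	R386M	potential_driver
FBXW7	E192A	potential_driver
FGFR2	V395D	potential_driver
ATM	L1420F	potential_driver
APC	S1400L	potential_driver
RB1	E137D	potential_driver
KRAS	D33E	potential_driver
ATM	S49C	passenger
ATM	P604S	passenger
APC	V1822D	passenger
APC	A545T	passenger
ARID1A	P1326S	passenger
RB1	N123S	passenger
PIK3CA	I391M	passenger
PIK3CA	V71I	passenger
PTEN	A79T	passenger
KRAS	R161Q	passenger
TP53	N235S	passenger
CTNNB1	A295V	passenger
FBXW7	I347V	passenger
FGFR2	M186T	passenger
PIK3R1	E137K	passenger
PTEN	T319T	passenger
PTEN	L70L	passenger
PIK3CA	T1025T	passenger
TP53	R213R	passenger
KRAS	G60G	passenger
CTNNB1	L148L	passenger
ARID1A	P224P	passenger
FBXW7	A509A	passenger
FGFR2	T341T	passenger
ATM	D126D	passenger
APC	T1493T	passenger
RB1	L688L	passenger
PIK3R1	G376G	passenger
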