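# Published per-gene mutation counts by allele-fraction bin
# (<=5%, 5.01-10%, >=10.01%) for the lavage cell-pellet and cfDNA fractions,
# with per-gene unique-patient and cancer-diagnosed-patient counts.
gene	pellet_low	pellet_mid	pellet_high	cfdna_low	cfdna_mid	cfdna_high	unique_patients	cancer_patients
PTEN	17	1	4	20	0	4	8	5
KRAS	16	1	2	10	1	1	7	6
PIK3CA	28	6	2	31	1	2	14	10
TP53	7	2	0	4	1	2	3	2
PIK3R1	7	1	0	10	0	0	3	2
FGFR2	3	2	0	3	0	0	2	2
FBXW7	5	1	1	4	0	0	1	1
CTNNB1	1	1	1	4	2	0	2	2
ATM	1	1	0	4	1	0	1	1
APC	1	0	0	2	0	0	1	1
ARID1A	3	0	1	2	0	2	3	1
RB1	1	0	1	0	0	2	2	1
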