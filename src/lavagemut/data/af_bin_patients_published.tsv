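# Published cancer-patient / total-patient counts per fraction x AF bin
# (bottom row of the per-gene AF-bin table).
fraction	bin	cancer_patients	total_patients
cell_pellet	low	4	43
cell_pellet	mid	3	11
cell_pellet	high	2	4
cfdna	low	5	33
cfdna	mid	1	4
cfdna	high	3	4
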