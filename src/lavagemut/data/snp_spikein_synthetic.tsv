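# Synthetic stand-in germline SNP fingerprint panel (24 high-MAF autosomal
# loci; the study's spike-in loci are not listed). 1-based positions, GRCh37.
locus_id	chrom	pos	ref	alt	maf
fp13	2	80989855	C	A	0.474
fp01	2	118846406	A	G	0.462
fp14	6	57774950	G	T	0.473
fp02	6	80817178	G	A	0.393
fp03	7	50859171	C	G	0.397
fp15	7	90571887	C	G	0.404
fp04	8	23832657	C	T	0.373
fp16	8	108770218	T	G	0.379
fp05	9	58210349	G	C	0.373
fp17	9	60512047	C	T	0.444
fp18	14	44000035	T	G	0.43
fp06	14	52790855	A	C	0.48
fp19	15	16654933	T	C	0.368
fp07	15	107229342	C	T	0.414
fp08	16	23994431	G	A	0.373
fp20	16	29279446	C	T	0.398
fp09	18	42501812	C	T	0.395
fp21	18	44845293	G	A	0.426
fp10	19	30813614	G	T	0.391
fp22	19	101616859	T	C	0.357
fp23	20	88091009	A	T	0.466
fp11	20	99943682	T	C	0.43
fp24	22	66480316	G	C	0.414
fp12	22	108329849	G	T	0.369
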