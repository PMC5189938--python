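# Synthetic stand-in amplicon coordinates for the 12-gene endometrial panel
# (102 amplicons of 138 bp inside the true GRCh37 gene spans; the study's
# amplicon loci are not publicly deposited). Columns: chrom start end name gene.
1	27022894	27023032	ARID1A_amp01	ARID1A
1	27031450	27031588	ARID1A_amp02	ARID1A
1	27040006	27040144	ARID1A_amp03	ARID1A
1	27048562	27048700	ARID1A_amp04	ARID1A
1	27057118	27057256	ARID1A_amp05	ARID1A
1	27065674	27065812	ARID1A_amp06	ARID1A
1	27074230	27074368	ARID1A_amp07	ARID1A
1	27082786	27082924	ARID1A_amp08	ARID1A
1	27091342	27091480	ARID1A_amp09	ARID1A
1	27099898	27100036	ARID1A_amp10	ARID1A
3	41236328	41236466	CTNNB1_amp01	CTNNB1
3	41249352	41249490	CTNNB1_amp02	CTNNB1
3	41262376	41262514	CTNNB1_amp03	CTNNB1
3	41275400	41275538	CTNNB1_amp04	CTNNB1
3	41288424	41288562	CTNNB1_amp05	CTNNB1
3	178866311	178866449	PIK3CA_amp01	PIK3CA
3	178873930	178874068	PIK3CA_amp02	PIK3CA
3	178881549	178881687	PIK3CA_amp03	PIK3CA
3	178889168	178889306	PIK3CA_amp04	PIK3CA
3	178896787	178896925	PIK3CA_amp05	PIK3CA
3	178904406	178904544	PIK3CA_amp06	PIK3CA
3	178912025	178912163	PIK3CA_amp07	PIK3CA
3	178919644	178919782	PIK3CA_amp08	PIK3CA
3	178927263	178927401	PIK3CA_amp09	PIK3CA
3	178934882	178935020	PIK3CA_amp10	PIK3CA
3	178942501	178942639	PIK3CA_amp11	PIK3CA
3	178950120	178950258	PIK3CA_amp12	PIK3CA
4	153242410	153242548	FBXW7_amp01	FBXW7
4	153278016	153278154	FBXW7_amp02	FBXW7
4	153313622	153313760	FBXW7_amp03	FBXW7
4	153349228	153349366	FBXW7_amp04	FBXW7
4	153384834	153384972	FBXW7_amp05	FBXW7
4	153420440	153420578	FBXW7_amp06	FBXW7
5	67511584	67511722	PIK3R1_amp01	PIK3R1
5	67523859	67523997	PIK3R1_amp02	PIK3R1
5	67536134	67536272	PIK3R1_amp03	PIK3R1
5	67548409	67548547	PIK3R1_amp04	PIK3R1
5	67560684	67560822	PIK3R1_amp05	PIK3R1
5	67572959	67573097	PIK3R1_amp06	PIK3R1
5	67585234	67585372	PIK3R1_amp07	PIK3R1
5	112043195	112043333	APC_amp01	APC
5	112058595	112058733	APC_amp02	APC
5	112073995	112074133	APC_amp03	APC
5	112089395	112089533	APC_amp04	APC
5	112104795	112104933	APC_amp05	APC
5	112120195	112120333	APC_amp06	APC
5	112135595	112135733	APC_amp07	APC
5	112150995	112151133	APC_amp08	APC
5	112166395	112166533	APC_amp09	APC
10	89622870	89623008	PTEN_amp01	PTEN
10	89631926	89632064	PTEN_amp02	PTEN
10	89640982	89641120	PTEN_amp03	PTEN
10	89650038	89650176	PTEN_amp04	PTEN
10	89659094	89659232	PTEN_amp05	PTEN
10	89668150	89668288	PTEN_amp06	PTEN
10	89677206	89677344	PTEN_amp07	PTEN
10	89686262	89686400	PTEN_amp08	PTEN
10	89695318	89695456	PTEN_amp09	PTEN
10	89704374	89704512	PTEN_amp10	PTEN
10	89713430	89713568	PTEN_amp11	PTEN
10	89722486	89722624	PTEN_amp12	PTEN
10	123237844	123237982	FGFR2_amp01	FGFR2
10	123267841	123267979	FGFR2_amp02	FGFR2
10	123297838	123297976	FGFR2_amp03	FGFR2
10	123327835	123327973	FGFR2_amp04	FGFR2
11	108093211	108093349	ATM_amp01	ATM
11	108107859	108107997	ATM_amp02	ATM
11	108122507	108122645	ATM_amp03	ATM
11	108137155	108137293	ATM_amp04	ATM
11	108151803	108151941	ATM_amp05	ATM
11	108166451	108166589	ATM_amp06	ATM
11	108181099	108181237	ATM_amp07	ATM
11	108195747	108195885	ATM_amp08	ATM
11	108210395	108210533	ATM_amp09	ATM
11	108225043	108225181	ATM_amp10	ATM
12	25358180	25358318	KRAS_amp01	KRAS
12	25367287	25367425	KRAS_amp02	KRAS
12	25376394	25376532	KRAS_amp03	KRAS
12	25385501	25385639	KRAS_amp04	KRAS
12	25394608	25394746	KRAS_amp05	KRAS
13	48877883	48878021	RB1_amp01	RB1
13	48900145	48900283	RB1_amp02	RB1
13	48922407	48922545	RB1_amp03	RB1
13	48944669	48944807	RB1_amp04	RB1
13	48966931	48967069	RB1_amp05	RB1
13	48989193	48989331	RB1_amp06	RB1
13	49011455	49011593	RB1_amp07	RB1
13	49033717	49033855	RB1_amp08	RB1
17	7571720	7571858	TP53_amp01	TP53
17	7573077	7573215	TP53_amp02	TP53
17	7574434	7574572	TP53_amp03	TP53
17	7575791	7575929	TP53_amp04	TP53
17	7577148	7577286	TP53_amp05	TP53
17	7578505	7578643	TP53_amp06	TP53
17	7579862	7580000	TP53_amp07	TP53
17	7581219	7581357	TP53_amp08	TP53
17	7582576	7582714	TP53_amp09	TP53
17	7583933	7584071	TP53_amp10	TP53
17	7585290	7585428	TP53_amp11	TP53
17	7586647	7586785	TP53_amp12	TP53
17	7588004	7588142	TP53_amp13	TP53
17	7589361	7589499	TP53_amp14	TP53
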