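# TMPRSS6 pathogenic/likely pathogenic missense variants present in gnomAD
# with global minor allele frequencies. GRCh37 coordinates, chromosome 22.
# Protein positions use the 802-aa MANE canonical isoform numbering.
# The two start-codon rows (Met1Lys, Met1Ile) are typed start_lost but are
# counted with the missense class (counted_as column), matching the table's
# 40-missense total.
chrom	pos	ref	alt	hgvs_c	hgvs_p	consequence	classification	flags	counted_as	af_global
22	37494466	G	T	326C>A	Ala109Asp	missense	pathogenic			0.000007953
22	37494467	C	T	325G>A	Ala109Thr	missense	pathogenic			0.000003976
22	37492697	T	C	395A>G	Tyr132Cys	missense	pathogenic			0.000005758
22	37491614	A	G	608T>C	Ile203Thr	missense	pathogenic			0.00001608
22	37491613	T	C	609A>G	Ile203Met	missense	pathogenic			0.000004025
22	37491614	A	T	608T>A	Ile203Lys	missense	pathogenic			0.000004021
22	37485778	G	T	676C>A	Leu226Met	missense	pathogenic			0.000004077
22	37485747	C	G	707G>C	Cys236Ser	missense	pathogenic			0.00004799
22	37485747	C	T	707G>A	Cys236Tyr	missense	pathogenic			0.000004102
22	37485646	C	T	808G>A	Gly270Arg	missense	pathogenic			0.00002176
22	37482412	G	A	884C>T	Ser295Leu	missense	pathogenic			0.000007375
22	37480876	C	T	977G>A	Cys326Tyr	missense	pathogenic			0.000006391
22	37480819	G	A	1034C>T	Pro345Leu	missense	pathogenic			0.00001131
22	37471316	A	G	1201T>C	Cys401Arg	missense	pathogenic			0.000008036
22	37471291	T	C	1226A>G	Tyr409Cys	missense	pathogenic			0.000004
22	37471220	C	T	1297G>A	Gly433Arg	missense	pathogenic			0.000003981
22	37469593	C	T	1534G>A	Asp512Asn	missense	pathogenic			0.00003183
22	37469591	G	C	1536C>A	Asp512Glu	missense	pathogenic			0.000003979
22	37469590	C	T	1537G>A	Glu513Lys	missense	pathogenic			0.00001591
22	37466665	C	A	1700G>T	Arg567Leu	missense	pathogenic			0.000004018
22	37466665	C	T	1700G>A	Arg567His	missense	pathogenic			0.00003134
22	37466666	G	A	1699C>T	Arg567Cys	missense	pathogenic			0.00003215
22	37466624	A	G	1741T>C	Trp581Arg	missense	pathogenic			0.000003997
22	37466603	G	A	1762C>T	Arg588Trp	missense	pathogenic			0.00001599
22	37466602	C	T	1763G>A	Arg588Gln	missense	pathogenic			0.00001598
22	37466585	C	G	1780G>C	Gly594Arg	missense	pathogenic			0.00005675
22	37466584	C	G	1781G>C	Gly594Ala	missense	pathogenic			0.000003991
22	37466585	C	A	1780G>T	Gly594Trp	missense	pathogenic			0.00003193
22	37466578	G	A	1787C>T	Ala596Val	missense	pathogenic			0.00003188
22	37466579	C	T	1786G>A	Ala596Thr	missense	pathogenic			0.000004002
22	37466576	G	A	1789C>T	Leu597Phe	missense	pathogenic			0.000007982
22	37465232	A	C	1994T>G	Leu665Arg	missense	pathogenic			0.000004545
22	37465149	A	G	2077T>C	Cys693Arg	missense	pathogenic			0.000006261
22	37462272	A	G	2257T>C	Ser753Pro	missense	pathogenic			0.000007297
22	37462263	G	C	2266C>G	Pro756Ala	missense	pathogenic			0.00002173
22	37462262	G	A	2267C>T	Pro756Leu	missense	pathogenic			0.00001448
22	37462236	G	A	2293C>T	Arg765Cys	missense	pathogenic			0.00002154
22	37462235	C	T	2294G>A	Arg765His	missense	pathogenic			0.00002154
22	37499456	A	T	2T>A	Met1Lys	start_lost	pathogenic		missense	0.000003977
22	37499455	C	T	3G>A	Met1Ile	start_lost	pathogenic		missense	0.000003977
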