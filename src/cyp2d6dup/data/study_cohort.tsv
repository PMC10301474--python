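dataset	genotype	n_cases	phenotype	activity_score	n_het_snvs	cnv_promoter	cnv_intron6	cnv_exon9	score_consistent
main	*1/*4×2	11	Intermediate	1	3	3	3	3	1
main	*1×2/*4	7	Normal	2	3	3	3	3	1
main	*1×2/*41	6	Ultrarapid	2.5	3	3	3	3	1
main	*1/*2×2	6	Ultrarapid	3	2	3	3	3	1
main	*4×2/*17	5	Intermediate	0.5	4	3	3	3	1
main	*2A×2/*41	4	Ultrarapid	2.5	2	3	3	3	1
main	*1×2/*9	4	Ultrarapid	2.5	1	3	3	3	1
main	*2A×2/*4	3	Normal	2	4	3	3	3	1
main	*2A×2/*17	2	Ultrarapid	2.5	2	3	3	3	1
main	*1/*41×2	2	Normal	2	3	3	3	3	1
main	*2×2/*9	2	Ultrarapid	2.5	3	3	3	3	1
main	*2×2/*2A	2	Ultrarapid	3	1	3	3	3	1
main	*1×2/*10	2	Normal	2.25	2	3	3	3	1
main	*4/*35×2	1	Normal	2	3	3	3	3	1
main	*27×2/*41	1	Ultrarapid	2.5	2	3	3	3	1
main	*9/*35×2	1	Ultrarapid	2.5	5	3	3	3	1
main	*4×2/*59	1	Intermediate	0.5	4	3	3	3	1
main	*4×2/*41	1	Intermediate	0.5	4	3	3	3	1
main	*4×2/*35	1	Intermediate	1	5	3	3	3	1
main	*2×2/*35	1	Ultrarapid	3	2	3	3	3	1
main	*2×2/*4	1	Normal	2	1	3	3	3	1
main	*2A×2/*29	1	Ultrarapid	2.5	2	3	3	3	1
main	*2A×2/*10	1	Normal	2.25	3	3	3	3	1
main	*2A×2/*9	1	Ultrarapid	2.5	4	3	3	3	1
main	*2A×2/*6	1	Normal	2	4	3	3	3	1
main	*2A/*4×2	1	Intermediate	1	4	3	3	3	1
main	*2/*4×2	1	Intermediate	1	3	3	3	3	1
main	*1×2/*6	1	Normal	2	1	3	3	3	1
main	*1×2/*3	1	Normal	2	1	3	3	3	1
main	*1/*2A×2	1	Ultrarapid	3	3	3	3	3	1
exploratory	*68+4/*41×2	2	Intermediate	1	4	4	3	3	1
exploratory	*1×2/*68+*4	2	Normal	2	3	4	3	3	1
exploratory	*2A×2/*68+*4	1	Normal	2	4	4	3	3	1
exploratory	*1×N/*68+*4	1	Ultrarapid	>3	3	6	6	5	1
exploratory	*13+*2A×2/*9	1	Ultrarapid	2.5	4	3	4	4	1
exploratory	*1×2/*36+*10	1	Normal	2	2	4	4	3	0
exploratory	*4×2/*29×2	1	Intermediate	0.5	4	4	4	4	0
exploratory	*2A×2/*2+*17 or *2A×2+*2/*17	1	Ultrarapid	3.5	2	4	4	4	1
exploratory	*2A×2/*4	1	Normal	2	4	14	3	3	1
ambiguous	*1/*6	1	Intermediate	1	1	2	2	2	1
ambiguous	*2A/*35	1	Normal	2	1	2	2	2	1
ambiguous	*9/*35	1	Normal	1.5	5	2	2	2	1
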