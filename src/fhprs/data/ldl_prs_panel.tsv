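# LDL-C polygenic score panel, version ldl12-v1
# 12-SNP / 6-SNP LDL-C raising score: 10 directly weighted SNPs plus the two
# APOE epsilon-defining SNPs (rs429358, rs7412) whose contribution enters
# through the diplotype weight block below.
# Frequencies are minor-allele frequencies per study group, as published
# (3 decimals, no renormalization). risk_is_minor records whether the
# LDL-raising (risk) allele is the minor allele in the reference cohort.
# APOE SNP rows carry no per-allele weight (weight = NA); their allele columns
# give minor/common alleles for genotype extraction only.
[panel]
version	ldl12-v1
[variants]
rsid	gene	risk_allele	other_allele	weight	in_6snp	risk_is_minor	maf_control	maf_fh_neg	maf_fh_pos
rs2479409	PCSK9	G	A	2.01	no	yes	0.358	0.400	0.388
rs629301	CELSR2	T	G	5.65	yes	no	0.244	0.180	0.166
rs1367117	APOB	A	G	4.05	yes	yes	0.241	0.317	0.285
rs4299376	ABCG8	G	T	2.75	yes	yes	0.271	0.311	0.290
rs1564348	SLC22A1	T	C	0.56	no	no	0.163	0.178	0.184
rs1800562	HFE	G	A	2.22	no	no	0.020	0.014	0.020
rs3757354	MYLIP	C	T	1.43	no	no	0.246	0.224	0.280
rs11220462	ST3GAL4	A	G	1.95	no	yes	0.101	0.120	0.109
rs8017377	NYNRIN	A	G	1.14	no	yes	0.348	0.373	0.399
rs6511720	LDLR	G	T	6.99	yes	no	0.134	0.058	0.111
rs429358	APOE	C	T	NA	yes	yes	0.139	0.215	0.153
rs7412	APOE	T	C	NA	yes	yes	0.070	0.018	0.023
[apoe_diplotypes]
diplotype	weight	freq_control	freq_fh_neg	freq_fh_pos
E2E2	-34.75	0.007	0.008	0.000
E2E3	-15.45	0.107	0.012	0.041
E2E4	-7.72	0.020	0.004	0.005
E3E3	0.00	0.624	0.556	0.601
E3E4	3.86	0.225	0.305	0.207
E4E4	7.72	0.017	0.045	0.031
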