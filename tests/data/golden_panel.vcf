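##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##source=antagwas
##contig=<ID=2L,length=2114>
##contig=<ID=X,length=1659>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	L000	L001	L002
2L	471	2L_471	C	G	.	.	.	GT:DP:GQ	1:44:66	0:36:59	1:53:54
2L	542	2L_542	A	G	.	.	.	GT:DP:GQ	1:67:58	0:37:67	1:50:66
2L	818	2L_818	C	A	.	.	.	GT:DP:GQ	1:32:63	1:35:80	0:32:58
2L	1114	2L_1114	G	A	.	.	.	GT:DP:GQ	1:39:58	0:51:53	0:45:73
X	62	X_62	C	A	.	.	.	GT:DP:GQ	1:35:57	0:44:47	1:41:51
X	257	X_257	C	G	.	.	.	GT:DP:GQ	0:49:72	1:36:79	0:37:60
X	328	X_328	A	C	.	.	.	GT:DP:GQ	0:39:64	1:37:68	1:38:60
X	659	X_659	A	T	.	.	.	GT:DP:GQ	0:42:60	1:36:64	1:32:68
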