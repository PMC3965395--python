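# The 24 miRNA genes over-represented in de novo CNVs on the enriched
# chromosomes (1 Loss, 2 Loss, 22 Gain) of the APL autism dataset.
# Coordinates are GRCh37, 1-based inclusive (miRBase primary transcripts).
# in_dgv = 1 if the locus also overlaps a CNV reported for the general
# population in the Database of Genomic Variants, 0 if study-specific.
gene_id	chrom	start	end	strand	size_bp	in_dgv	n_patients	cnv_types
hsa-mir-2682	1	98510798	98510907	-	110	1	1	Loss
hsa-mir-137	1	98511626	98511727	-	102	1	1	Loss
hsa-mir-200b	1	1102484	1102578	+	95	1	1	Loss
hsa-mir-200a	1	1103243	1103332	+	90	1	1	Loss
hsa-mir-429	1	1104385	1104467	+	83	1	1	Loss
hsa-mir-2467	2	240273419	240273499	-	81	1	2	Loss
hsa-mir-3133	2	242417320	242417397	+	78	1	2	Loss
hsa-mir-4436b-2	2	111042430	111042520	+	91	0	1	Loss
hsa-mir-4440	2	239990513	239990610	-	98	1	2	Loss
hsa-mir-4441	2	240007523	240007622	-	100	1	2	Loss
hsa-mir-4786	2	240882432	240882511	-	80	1	2	Loss
hsa-mir-4267	2	110827538	110827619	-	82	1	1	Loss
hsa-mir-4436b-1	2	110844010	110844100	-	91	0	1	Loss
hsa-mir-4269	2	240227157	240227240	+	84	1	2	Loss
hsa-mir-149	2	241395418	241395506	+	89	1	2	Loss
hsa-mir-3618	22	20073269	20073356	+	88	1	3	Gain;Loss
hsa-mir-1306	22	20073581	20073665	+	85	1	3	Gain;Loss
hsa-mir-301b	22	22007270	22007347	+	78	1	2	Gain
hsa-mir-130b	22	22007593	22007674	+	82	1	2	Gain
hsa-mir-4761	22	19951276	19951357	+	82	1	3	Gain;Loss
hsa-mir-185	22	20020662	20020743	+	82	1	3	Gain;Loss
hsa-mir-1286	22	20236657	20236734	-	78	1	3	Gain;Loss
hsa-mir-649	22	21388465	21388561	-	97	1	3	Gain;Loss
hsa-mir-650	22	23165270	23165365	+	96	1	2	Gain
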