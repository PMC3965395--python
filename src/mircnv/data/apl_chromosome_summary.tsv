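# Per-chromosome mapping summary for 178 de novo CNVs (118 Losses, 60 Gains)
# from 192 autism patients (the APL dataset), GRCh37 coordinates.
# ratio1 = summed miRNA gene length / chromosome length;
# gain_ratio2 / loss_ratio2 = union length of CNVs of that type / chromosome length;
# gain_hits / loss_hits = total miRNA-gene-in-CNV overlap incidences.
# NA marks chromosome/type cells with no de novo CNVs in the dataset.
chrom	length_bp	n_mirna_genes	ratio1	gain_ratio2	gain_hits	loss_ratio2	loss_hits
1	249250621	127	4.05e-5	0.0241	5	0.0050	5
2	243199373	98	3.10e-5	0.0009	0	0.0314	17
3	198022430	76	3.21e-5	0.0041	1	0.0923	12
4	191154276	56	2.31e-5	NA	NA	0.0886	4
5	180915260	67	3.03e-5	NA	NA	0.0763	7
6	171115067	54	2.56e-5	0.0019	0	0.0187	2
7	159138663	67	3.41e-5	0.0103	4	0.1425	7
8	146364022	70	3.54e-5	0.0068	0	0.0088	1
9	141213431	71	3.95e-5	0.0371	9	0.0297	1
10	135534747	61	3.66e-5	0.0822	4	0.0005	0
11	135006516	69	4.03e-5	0.0002	0	0.0410	0
12	133851895	57	3.48e-5	0.1691	13	0.1013	3
13	115169878	37	2.62e-5	0.0009	0	0.0169	0
14	107349540	88	6.58e-5	0.0006	0	NA	NA
15	102531392	57	4.68e-5	0.1254	39	0.0742	7
16	90354753	48	4.40e-5	0.0320	2	0.1032	9
17	81195210	83	7.89e-5	0.0317	8	0.0256	1
18	78077248	30	2.74e-5	0.0006	0	0.2618	2
19	59128983	108	1.47e-4	NA	NA	0.0145	2
20	63025520	40	5.16e-5	NA	NA	0.0301	2
21	48129895	15	2.65e-5	0.0074	1	0.1183	3
22	51304566	36	5.59e-5	0.0893	18	0.1473	24
X	155270560	108	5.77e-5	0.0304	8	0.0406	1
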