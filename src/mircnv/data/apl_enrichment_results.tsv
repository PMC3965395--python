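# Published FDR-adjusted p-values of the per-chromosome randomization test
# on the APL de novo CNV dataset (10^6 realizations per chromosome and type).
# unique = distinct miRNA genes overlapped; hits = overlap incidences.
# NA marks chromosome/type cells with no de novo CNVs.
chrom	gain_unique	gain_hits	gain_p_fdr	loss_unique	loss_hits	loss_p_fdr
1	5	5	0.45204	5	5	0.02309
2	0	0	0.84211	10	17	0.00449
3	1	1	0.45642	10	12	0.64896
4	NA	NA	NA	4	4	0.98516
5	NA	NA	NA	7	7	0.73942
6	0	0	0.84211	2	2	0.70911
7	2	4	0.17818	6	7	1
8	0	0	0.84211	1	1	0.70911
9	9	9	0.17818	1	1	0.98516
10	3	4	0.84211	0	0	1
11	0	0	0.84211	0	0	1
12	13	13	0.46568	3	3	1
13	0	0	0.84211	0	0	1
14	0	0	0.84211	NA	NA	NA
15	11	39	0.17818	6	7	0.70911
16	2	2	0.84211	8	9	0.70911
17	8	8	0.13920	1	1	1
18	0	0	0.84211	2	2	1
19	NA	NA	NA	2	2	0.64896
20	NA	NA	NA	2	2	0.64896
21	1	1	0.17818	3	3	0.64896
22	9	18	0.04349	9	24	0.07785
X	8	8	0.19599	1	1	1
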