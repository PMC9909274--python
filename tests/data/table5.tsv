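# Per-complex interface-ranking outcomes of a 28-complex test set:
# NPIRP L0 (interfaces hit) and L1 (total true pairs found) at four
# top-t depths.
pdb_id	l0_t10	l1_t10	l0_t15	l1_t15	l0_t20	l1_t20	l0_t30	l1_t30
1DD3	2	3	2	6	4	8	4	14
1F5Z	0	0	2	2	4	4	4	9
1J2W	2	2	2	4	3	6	4	11
1NSW	4	13	4	14	5	22	5	31
1P27	1	2	2	6	2	8	2	12
1QVC	0	0	3	3	3	3	6	12
1QYN	4	8	5	12	6	16	6	21
1REW	2	4	2	5	2	9	2	16
1SWF	4	15	5	18	6	22	6	26
1UDD	2	2	2	2	2	4	3	7
1UFQ	2	5	4	7	4	9	4	13
1WYT	1	1	1	2	2	3	2	3
1ZXJ	0	0	0	0	0	0	0	0
2A2U	2	2	2	2	2	2	4	4
2EPI	6	9	6	12	6	14	6	19
2OZK	2	5	2	5	2	6	2	6
2Z8U	0	0	0	0	2	2	2	2
2ZIH	2	4	2	4	3	5	3	5
2ZME	3	3	3	3	3	7	4	11
2ZYZ	2	2	3	5	3	6	4	11
3HM0	4	8	6	13	6	14	6	17
3IBF	3	3	3	4	3	5	3	7
3ITY	4	4	4	5	4	5	4	5
3KYH	0	0	0	0	0	0	1	1
3SQO	1	1	1	1	1	1	2	2
3STB	4	13	4	14	4	15	5	22
3V15	3	7	3	9	3	12	3	17
3VH5	5	13	5	14	5	15	5	17
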