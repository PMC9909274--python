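# Per-complex chain-interaction bookkeeping of a 28-complex test set:
# a = correctly predicted interactions, b = correctly predicted
# non-interactions, pt_norm = a + b.  relationship: 1 = only interacting
# chain pairs, 2 = both kinds present.
pdb_id	a	b	pt_norm	relationship
1DD3	2	1	3	2
1F5Z	4	0	4	2
1J2W	5	0	5	1
1NSW	5	0	5	2
1P27	3	1	4	2
1QVC	6	0	6	1
1QYN	6	0	6	1
1REW	5	0	5	2
1SWF	5	0	5	1
1UDD	5	0	5	1
1UFQ	6	0	6	1
1WYT	6	0	6	1
1ZXJ	3	1	4	2
2A2U	6	0	6	1
2EPI	6	0	6	1
2OZK	5	0	5	2
2Z8U	5	0	5	2
2ZIH	5	0	5	2
2ZME	5	0	5	2
2ZYZ	5	0	5	2
3HM0	6	0	6	1
3IBF	6	0	6	1
3ITY	6	0	6	1
3KYH	5	0	5	2
3SQO	4	1	5	2
3STB	5	0	5	1
3V15	5	0	5	1
3VH5	4	0	4	1
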