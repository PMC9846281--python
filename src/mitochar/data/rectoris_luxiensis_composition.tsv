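partition	size_bp	t_pct	c_pct	a_pct	g_pct	at_pct	cg_pct	at_skew	gc_skew
ND1	972	26.3	28.8	30.5	14.4	56.8	43.2	0.07	-0.33
ND2	1044	24.2	30.8	32.8	12.2	57.0	43.0	0.15	-0.43
COX1	1548	29.8	25.3	27.8	17.0	57.6	42.3	-0.03	-0.20
COX2	690	27.1	25.8	31.4	15.7	58.5	41.5	0.07	-0.24
ATP8	165	26.1	26.7	36.4	10.9	62.5	37.6	0.16	-0.42
ATP6	684	30.0	26.5	30.7	12.7	60.7	39.2	0.01	-0.35
COX3	783	26.7	28.5	28.6	16.2	55.3	44.7	0.03	-0.28
ND3	348	39.3	28.7	27.6	14.4	66.9	43.1	-0.17	-0.33
ND4L	294	27.2	30.6	26.5	15.6	53.7	46.2	-0.01	-0.32
ND4	1380	27.2	26.9	32.1	13.7	59.3	40.6	0.08	-0.33
ND5	1821	28.5	26.1	32.9	12.5	61.4	38.6	0.07	-0.35
ND6	519	42.8	11.6	13.5	32.2	56.3	43.8	-0.52	0.47
CYTB	1140	29.6	26.3	29.8	14.2	59.4	40.5	0.00	-0.30
rRNAs	2593	19.7	24.4	35.2	20.7	54.9	45.1	0.28	-0.08
tRNAs	1556	24.9	24.5	31.1	19.5	56.0	44.0	0.11	-0.11
D-LOOP	921	33.6	19.1	33.7	13.7	67.3	32.8	0.00	-0.16
PCGs	11394	28.6	26.5	29.9	15.0	58.5	41.5	0.02	-0.28
Total	16592	26.2	26.2	32.0	15.7	58.2	41.9	0.10	-0.25
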