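gene	cluster	avg_log2FC	pct.1	pct.2	p_val_adj
INS	0	4.2	0.98	0.12	1e-200
IAPP	0	3.1	0.85	0.08	1e-150
MALAT1	0	0.4	0.99	0.95	0.3
GCG	1	4.8	0.97	0.15	1e-180
TTR	1	2.2	0.80	0.20	1e-60
SST	2	4.5	0.95	0.05	1e-120
RBP4	2	1.9	0.70	0.22	1e-40
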