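tissue	cell_type	gene	species
pancreas	beta cell	INS	both
pancreas	beta cell	IAPP	both
pancreas	beta cell	DLK1	both
pancreas	alpha cell	GCG	both
pancreas	alpha cell	TTR	both
pancreas	delta cell	SST	both
pancreas	delta cell	RBP4	both
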