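alias	canonical
# pancreatic islet single-letter conventions
a	alpha cell
b	beta cell
d	delta cell
e	epsilon cell
g	gamma cell
alpha	alpha cell
beta	beta cell
delta	delta cell
epsilon	epsilon cell
gamma	gamma cell
acinar	acinar cell
ductal	ductal cell
# immune-cell spelling variants
nk cell	natural killer cell
nk	natural killer cell
t-cell	t cell
b-cell	b cell
treg	regulatory t cell
dc	dendritic cell
macrophages	macrophage
monocytes	monocyte
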