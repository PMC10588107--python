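# clustercall

Cluster-level cell-type annotation for single-cell RNA-seq, driven by a
curated marker-gene database.

After the standard scRNA-seq pipeline (normalization → clustering →
per-cluster differential expression), each cluster still needs a biological
name. `clustercall` takes the per-cluster DE table — the layout produced by
Seurat's `FindAllMarkers` — and a tissue/cell-type marker catalogue, and
returns ranked cell-type predictions per cluster with the matched marker
genes as evidence. No reference expression atlas and no user-supplied
marker lists are needed; the database does that work. It is aimed at
analysts who have clusters and marker tables in hand and want fast,
reproducible, auditable labels.

## The method

For cluster *k* and gene *i*, with average log2 fold change $l_i^k$,
in-cluster detection fraction $p_i^k$ and out-of-cluster detection fraction
$p_i^{K\neg k}$:

1. **Filter** — keep genes with $p_i^k > 0.25$ and adjusted p-value
   $< 0.05$ (both strict).
2. **Composite gene score** —

   $$S_i^k = \frac{2^{l_i^k} \, p_i^k}{p_i^{K\neg k}}$$

   so $\log S_i^k$ is the log fold change plus the log prevalence ratio.
   A zero denominator is floored at `zero_floor` (default 0.001): a gene
   detected nowhere else is the strongest possible marker and must rank
   finitely high.
3. **Cell-type score** — against the database's binary membership
   indicator $d_{ic}$ (gene *i* marks cell type *c*):

   $$S_c^k = \frac{1}{I_k} \sum_{i=1}^{I_k} S_i^k \, d_{ic}$$

   where $I_k$ counts **all** retained genes of the cluster, matched or
   not — a cluster full of genes the database does not know scores low
   everywhere.
4. **Selection** — cell types are ranked by $S_c^k$; a cluster may receive
   several labels when their evidence is similar. The number of co-assigned
   types is the jump point of the sorted score sequence: the position of
   the largest drop between consecutive scores (ties toward fewer labels),
   capped at `max_n` (default 3).

Benchmarking follows the cluster-annotation convention: the rank-1 cell
type is the final call, accuracy is the proportion of *cells* (cluster
sizes as weights) in correctly labelled clusters, and F1 is computed per
reference cell type and averaged weighted by reference cell counts.
Reference and predicted names are harmonized through an editable synonym
table; ambiguous reference labels (e.g. `pp`, `MHC class II`) are excluded
from scoring entirely.

## Worked example

`demo/db.tsv` (long form: `tissue  cell_type  gene  species`) lists markers
for three pancreatic islet cell types; `demo/markers.tsv` is a Seurat-style
marker table for three clusters:

```sh
clustercall annotate --markers demo/markers.tsv --db demo/db.tsv \
    --tissue pancreas --out demo/run
```

prints

```
Cluster annotation summary
  clusters: 3   unassigned: 0   candidate cell types: 3
  thresholds: pct_in > 0.25, p_adj < 0.05, zero_floor 0.001, max_n 3

  cluster       I_k  predicted cell type(s)                        top score
  0               2  beta cell                                         120.6
  1               2  alpha cell                                        99.26
  2               2  delta cell                                        220.9
```

`I_k` is the number of genes per cluster surviving the filter (the
housekeeping gene `MALAT1` was dropped by the p-value rule, so cluster 0
keeps only INS and IAPP). The top score is the mean composite score of the
matched markers — e.g. for cluster 0, INS scores
$2^{4.2}\times 0.98 / 0.12 = 150.1$ and IAPP $91.1$, giving
$(150.1 + 91.1)/2 = 120.6$ for *beta cell*. The run directory contains
`predictions.tsv` (every candidate with raw and normalized scores and the
selected flag), `evidence.tsv` (which genes drove each call and their
$S_i^k$), a `run.log` with the full effective configuration, and a dot
plot (`dotplot.png`/`.svg`) of clusters × candidate cell types.

The same pipeline as a library:

```python
from clustercall import CellTypeAnnotator

model = CellTypeAnnotator.from_files("demo/markers.tsv", "demo/db.tsv",
                                     tissue="pancreas")
result = model.fit()
print(result.summary())
result.ranked      # tidy per-(cluster, candidate) score table
result.evidence    # matched marker genes per selected cell type
```

Other subcommands: `clustercall db-qc` (database summary and quality
flags), `clustercall evaluate` (accuracy/F1 against reference labels),
`clustercall make-fixtures` (synthetic scenario with planted ground truth).

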