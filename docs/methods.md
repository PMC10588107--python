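# Methods

## Model

`clustercall` annotates whole clusters, not individual cells. Its only
modelling assumption is the marker-gene hypothesis: a good marker is highly
expressed in its cell type and rarely detected in unrelated cells. The
input is therefore not an expression matrix but the summary statistics an
upstream differential-expression step already produced per (cluster, gene):
average log2 fold change `l`, in-cluster detection fraction `p_in`,
out-of-cluster detection fraction `p_out`, and an adjusted p-value. The DE
step itself (normalization, clustering, testing) is out of scope and its
choices propagate into the annotation — garbage marker tables yield garbage
labels.

The composite gene score `S_i = 2**l * p_in / p_out` multiplies the fold
change by the prevalence ratio; its log is the sum of the log fold change
and the log prevalence change, so the score rewards genes that are both
strongly up-regulated and selectively detected. The cell-type score
averages the matched gene scores over *all* retained genes of the cluster
(`S_c = sum(S_i * d_ic) / I_k` with `d_ic` the database membership
indicator). Keeping unmatched genes in the denominator is deliberate: it is
what makes scores comparable across clusters and penalizes clusters whose
DE signature the database cannot explain. The score is covariant under a
common rescaling of a cluster's gene scores, so rankings within a cluster
are unaffected by global effect-size inflation.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `pct_threshold` | 0.25 | minimum in-cluster detection fraction (strict `>`) |
| `alpha` | 0.05 | maximum adjusted p-value (strict `<`) |
| `zero_floor` | 0.001 | replaces `p_out = 0` in the score denominator |
| `max_n` | 3 | cap on co-assigned cell types per cluster |

The filter thresholds use strict inequalities; rows exactly at 0.25 or 0.05
are dropped. `zero_floor` trades off between "a gene detected nowhere else
is infinitely diagnostic" (floor → 0) and numerical sanity; 0.001 keeps
such genes at the top of the ranking (a never-elsewhere gene scores 1000×
its fold-change term) without infinities. Neither selection nor ranking
depends on the per-cluster *normalized* scores; those exist only for the
dot plot.

## Multi-assignment (jump point)

A cluster with genuinely similar evidence for several cell types (e.g.
closely related T-cell subsets) should not be forced into one label. The
number of co-assigned types is chosen by a jump-point rule on the sorted
score sequence. Jump-point criteria in this literature are often phrased
through the cumulative variance of the score sequence, and the exact
procedure varies between tools and is rarely fully specified; this package
therefore fixes one explicit, documented interpretation: over positions m
in the positive-score prefix, compute the gap `s[m] − s[m+1]`; n is the
position of the largest gap, first occurrence winning ties (so ambiguity
resolves toward fewer labels), capped at `max_n`. This matches the intent —
co-assign when evidence is similar, cut where evidence drops — and is
deterministic and trivially auditable. It is a design choice, not a
universal convention; other annotation tools may co-assign different n for
clusters with flat score profiles.

Ties in the ranking itself are broken lexicographically by
(tissue, cell type) so output is identical across platforms and runs.
All-zero clusters (nothing retained, or nothing matched) are reported
explicitly as `unassigned` with a reason rather than silently dropped, and
`unassigned` always counts as incorrect in evaluation.

## Database conventions

The catalogue is a long-form table (tissue, cell type, gene, species);
a wide binary genes × `tissue:cell_type` layout is accepted for
interoperability and transposed on load. The cell-type universe is the set
of distinct (tissue, cell type) pairs — the same name in two tissues is two
cell types. Gene matching is case-insensitive through an upper-cased key
(human `INS1` and mouse `Ins1` collapse), with display casing preserved;
alias resolution is an optional, user-supplied two-column file applied at
load time — no live lookups, for reproducibility. Exact duplicate records
are deduplicated with a logged count.

QC reports two totals because the field counts markers two ways:
`n_marker_rows` counts distinct (tissue, cell type, gene) rows, and
`n_marker_entries` counts species tracks, i.e. a record valid for both
human and mouse counts twice. Per-cell-type marker statistics (min / mean /
max) use the unified rows. For a catalogue of 340 cell types with 14,892
unified rows of which 11,595 are dual-species, these conventions give a
mean of exactly 43.8 markers per cell type and 26,487 species-track
entries — the decomposition that makes the two published-style totals
mutually consistent. Quality flags report the fraction of tissues with more
than 6 cell types and of cell types with more than 4 markers.

## Evaluation protocol

Predictions are collapsed to the rank-1 cell type per cluster. Reference
and predicted labels are canonicalized (trim, case-fold, plural `cells` →
`cell`, then one application of an editable synonym table which must be
idempotent); clusters whose reference label is on the exclusion list are
removed from every numerator and denominator. Two accuracies are reported,
because both conventions appear in practice: cell-weighted (fraction of
cells in correct clusters) and per-cluster (fraction of clusters correct).
F1 is computed per reference cell type from cell-weighted cluster
assignments — a correct cluster is a TP for its type; a wrong one is an FN
for its reference type and an FP for its predicted type — and aggregated
weighted by reference cell counts. Micro/macro alternatives exist; the
weighted choice keeps rare types from dominating while still reporting
their individual rows in `per_celltype`.

## Synthetic data

The generator works at the tool's input boundary: it fabricates marker
tables, not count matrices, so no DE step is simulated. Each cluster is
planted on one database cell type; signal rows draw from that type's
markers with log2 fold change in [1, 3], in-cluster detection in
[0.4, 0.9], out-of-cluster detection in [0.01, 0.1] and adjusted p-values
log-uniform in [1e-50, 1e-3] — the profile of strong curated markers.
Noise rows (fraction `noise_fraction`) alternate between markers of other
cell types and novel symbols, use weak background ranges, and cycle through
three fates (fail the detection filter, fail the significance filter, pass
both) so the filter always has non-trivial work. Generation is a pure
function of the config; the same seed reproduces byte-identical TSV
exports.

What passing the synthetic suite shows — and does not. Planted-truth
recovery demonstrates that the scoring machinery ranks the generating cell
type first when markers behave as curated markers should. Real data differ
in ways the generator does not emulate: correlated marker sets between
related cell types, doublet-driven mixed signatures, ambient RNA inflating
`p_out`, database incompleteness, and DE-step artefacts. Perfect synthetic
recovery is therefore a correctness statement about the implementation, not
a performance claim about real tissues. Under the generator's background
noise model the planted signal dominates strongly, so mean recovery can
remain at 100% even at high noise fractions; the recovery curve is
validated as monotone non-increasing in noise (and non-decreasing in signal
strength), not as strictly falling.

A separate generator, `make_reference_like_database`, produces a
**synthetic** catalogue with the summary shape of a large curated
human/mouse database (28 tissues, 340 cell types, per-type marker counts
min 4 / max 300 / mean 43.8, 26,487 species-track entries). Its gene
symbols and cell-type names are fabricated; it exists to exercise QC and
scale, never to annotate real data.

## Numerical choices

- `2**l` is computed with scalar pow per element; the result is
  bit-identical to a plain evaluation of the formula (vectorized SIMD pow
  can differ in the final ulp).
- Cell-type scores are a matched-gene dot product divided by the integer
  `I_k`; agreement with triple-loop evaluation is exact for
  order-independent inputs and within ~1e-14 relative otherwise.
- Problem sizes: the test suite and the acceptance script use 8-cluster /
  8-cell-type scenarios, 10 seeds and 1000-instance formula sweeps — large
  enough to exercise every code path and tie-break while keeping a full
  run in seconds.
- Degenerate inputs: empty databases, marker tables with no database
  overlap, clusters emptied by the filter, and all-zero score rows each
  produce a defined result (error, warning + unassigned, or flagged
  unassigned) rather than silent propagation.

## Limitations

- Cannot discover cell types absent from the database; the closest-match
  evidence is returned for manual inspection instead.
- Cluster-level only: heterogeneous clusters get one (or up to `max_n`)
  labels for all their cells; fixing that requires re-clustering, not a
  different scorer.
- The jump-point rule is an interpretation (see above).
- Annotation quality is bounded by the upstream DE table and by database
  coverage of the tissue under study.
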