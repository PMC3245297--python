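# Methods

`kinevo` reconstructs how substrate specificities evolve inside a large,
multi-functional enzyme family, with the FGGY carbohydrate kinases — a
family of two-domain ATP-dependent sugar kinases covering at least nine
specificities (glycerol kinase GlpK, xylulokinase XylB, L-ribulokinase
AraB, ...) — as the packaged worked case.  This note records the models,
the parameters that matter, and the design choices made where the design
was genuinely open.

## Context-gated annotation propagation

Homology at the family's working threshold (30% identity) is too weak to
assign a substrate on its own.  A candidate annotation is therefore
confirmed only when two independent lines of evidence agree:

1. best-hit identity to a literature-verified reference protein of at
   least `identity_threshold` (default 0.30, global alignment, BLOSUM62,
   gap open 11 / extend 1; identity denominator = shorter sequence, so the
   measure is UCLUST-like);
2. at least one pathway partner of the reference's function (isomerase,
   epimerase, transporter, downstream enzyme) inside the candidate's
   operon.

Operons are reconstructed from coordinates: consecutive same-strand genes
on one contig with intergenic gaps of at most `max_gap_bp` (default 300
bp, the standard prokaryotic heuristic).  The genome-wide partner count
("functional context") is always reported; a configurable flag lets it
substitute for operon support, but the default is strict because operon
co-localisation is the stronger signal.  Regulon evidence is not modelled.

Identity clustering uses a greedy centroid scheme: sequences processed in
decreasing length (id-lexicographic ties), each joining the first centroid
at or above the threshold, otherwise founding a cluster.  The ordering
rule exists only to make clustering deterministic; at a coarse 30%
threshold the scoring details are insensitive.

## SDP scoring

A specificity-determining position (SDP) is an alignment column conserved
within each isofunctional group but different between groups.  Each column
is scored by the plug-in mutual information (bits, log base 2) between
residue identity and group label over the column's non-gapped rows; gaps
are excluded from the counts because they reflect alignment, not
chemistry.  Significance is calibrated by permutation: group labels are
shuffled across rows `n_perm` times (default 999) and each column gets a
z-score and the add-one permutation p-value `(1 + #{null >= obs}) /
(1 + n_perm)`.  Columns are ranked by descending z (ties: descending MI,
then column index).

The number of significant columns is the global minimum of a Bernoulli
(union-bound) estimator over the ascending p-values, `B(k) = min(1,
C(L,k) p_(k)^k)`, with `k* = 0` when the minimum never drops below 1.
This estimator is deliberately isolated behind one function
(`sdp.bernoulli_cutoff`) so an alternative rule can be swapped in.  Two
calibration facts worth knowing:

* Under a label-shuffled null the p-values are uniform to KS-test
  precision (verified by the acceptance suite), which means the estimator
  is *not* a strict false-positive guard: `B(1) = L·p_(1)` dips below 1
  whenever the smallest of L uniform p-values falls under 1/L, which
  happens in roughly 63% of null data sets.  The cutoff is a ranking
  device; the structural filter below is what removes false positives.
* More sophisticated MI variants (background smoothing,
  substitution-matrix weighting, sequence weighting for redundancy) are
  intentionally not implemented; the permutation z absorbs most of what
  they correct for at desk scale.

When a group spans several low-identity clusters, scoring runs on the
largest cluster per group and the ranked columns are carried to the other
clusters through the master alignment (`family_io.map_column_to_master`),
which matches non-gap residue ordinals of a shared row.

## Structural filter and the dual criterion

For every ligand-bound structure, the per-residue distance to the ligand
is the minimum heavy-atom pair distance (the standard binding-site
convention; side-chain-only and CB-only variants are available by flag).
Structure residues map to master columns through a global alignment of the
structure-derived sequence against the degapped master row; 90% identity
over the aligned span is required, tolerating point mutations in
crystallisation constructs.  Distances are averaged per column across all
contributing complexes; structures lacking the relevant ligand are skipped
with a warning.

A column is selected as an SDP only if it is **both** significant in the
sequence ranking **and** within `distance_cutoff` (default 4 Å) of the
ligand on average.  The two single-criterion failure modes are exactly
complementary: group-specific columns far from the ligand pass the ranking
but fail the distance; globally conserved catalytic columns sit at the
ligand but carry no group signal.  With no structures supplied the
selection degrades to sequence-only mode with an explicit warning — a
non-canonical fallback.

## Signatures, PWMs, networks

A protein's signature is its residues at the selected columns in sequence
order (length 5 in the packaged family; gaps kept as `-`).  Each cluster
gets a 20-row position weight matrix of raw per-column frequencies over
non-gap symbols — no pseudocounts, because the downstream comparison is
correlation, not log-odds scoring.  PWMs are compared by Pearson
correlation over the flattened 20×k entries (the 2-D `corr2` statistic)
and clustered at distance 1 − r with average linkage (a deliberate,
configurable choice; complete linkage is the R `hclust` default but
average linkage is less sensitive to single divergent clusters).
Correlation of a constant PWM is undefined and raises rather than
returning 0.  Logo heights use `log2(20) − H` per column, without
small-sample correction.

Similarity networks put an edge between two proteins when their pairwise
alignment beats an E-value threshold.  Full sequences use Smith–Waterman
local alignment (BLOSUM62, gap open 11 / extend 1); signatures, being
short and equal length, use an ungapped positional BLOSUM62 sum.  Raw
scores convert to bits with fixed ungapped Karlin–Altschul constants
(λ = 0.3176, K = 0.134) and to E-values as `m·n·2^(−bits)`.  These
E-values are *comparative* devices for threshold sweeps, not database
statistics; thresholds are swept over the achievable ladder rather than
interpreted absolutely.  Partition agreement between two networks is the
adjusted Rand index of their connected-component partitions over a fixed
node universe (isolates kept).

## Trees and origin counting

Externally inferred Newick trees are first-class inputs; the native
builder is canonical neighbour joining on p-distances, with bootstrap
support from column resampling (default 100 replicates, support scaled to
100).  Rooting places the root on the edge separating a designated
outgroup clade.

The central question — did each function arise once? — is answered by
Fitch small parsimony over unordered function states.  For each function
the reported origin count is the minimum, across most-parsimonious
reconstructions, of the number of edges whose child gains the state, plus
one if the root carries it; this makes "emerged only once" well defined
for the ancestral function.  Note one consequence of per-function
minimisation: on the fully interleaved quartet ((f1,f2),(f1,f2)) both
functions get origin 1, because either may be ancestral in some
most-parsimonious labeling.  Multifurcations are resolved
deterministically (smallest-tip-name order) before the dynamic program;
monophyly is tested directly and implies a single origin.

Species-tree projections average strains into species first (a species
with one of two strains carrying a function contributes 0.5), then report
per-taxon fractions of species carrying each function, with the taxon
taken from the named ancestor at a chosen collapse depth.

## The synthetic family

The generator's defaults are the package's study conditions: 2 groups ×
20 sequences, 200 columns, 5 planted SDPs, 3 catalytic columns, 3 distal
group-specific columns, within-group noise ε = 0.05.  Planted and distal
columns carry one distinct residue per group (flipped to a random other
residue with probability ε); catalytic columns carry one residue
conserved across all groups; background columns draw each row
independently from a per-column Dirichlet profile (concentration 0.5 per
residue) shared by all groups.  The concentration was chosen so background
columns look like moderately conserved family columns: their MI is small
but nonzero and their permutation p-values are uniform.  Toy structures
are CA-only chains with a single-atom ligand at the origin; binding
columns sit on a 3.5 Å shell and everything else at ≥ 8 Å, so the 4 Å
contract holds exactly.  Gene tables place each planted candidate in an
operon with a pathway partner (same strand, gap < 300 bp) and give decoys
a shuffled, non-partner neighbour.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: indels beyond planted gaps, rate heterogeneity
or any substitution-model evolution, phylogenetic correlation between
rows, and between-group divergence of background columns.  The last
omission matters: because backgrounds are shared across groups, full
sequences differ between groups only at the 8 group-specific columns
(≈ +52 BLOSUM62 score against ≈ 190 columns of pair noise), so the
full-sequence similarity network does not split into function components
at any threshold at this scale.  In real families the global sequence
divergence between isofunctional groups does the separating.  The
signature-sequence network, by contrast, recovers the function partition
essentially always.

## Numerical choices and problem sizes

* Permutation MI nulls are fully vectorised (one `bincount` per column
  over all permutations); a 200-column, 40-row ranking at n_perm = 999
  takes ≈ 0.35 s.
* Replicate counts in the test and acceptance machinery are 100 for the
  recovery-rate experiments and 200 trees for the parsimony oracle; these
  sizes give binomial standard errors of ≤ 5 points on the reported
  rates while keeping a full run in about a minute.
* Ties in ranking break by MI then column index; ties in the Bernoulli
  argmin take the smallest k; dendrogram ties follow input label order —
  every pipeline stage is deterministic given (config, seed).
* Degenerate inputs fail loudly: all-gap columns, single-group columns,
  constant PWMs, edgeless networks in purity, non-clade outgroups and
  asymmetric distance matrices all raise with specific messages.

## Known limitations

* The MI statistic ignores residue similarity (an R→K flip counts as much
  as R→D) and row redundancy.
* E-values are uncalibrated comparative scores.
* The Bernoulli cutoff is a ranking heuristic with a ~63% per-data-set
  chance of admitting at least one null column; the structural filter is
  the effective specificity control.
* Origin counting minimises per function independently; a joint
  reconstruction could not realise all minima simultaneously.
* No maximum-likelihood tree inference, no lateral-transfer
  reconciliation, no regulon modelling, no mmCIF parsing.
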