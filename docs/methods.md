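# Methods

This note records the models, rules and numerical choices behind merscape,
what the synthetic-data generator does and does not emulate, and the known
limitations.

## Data model and coordinates

Genomes are multi-replicon collections of CDS features. Internal
coordinates are 0-based half-open; GFF3 I/O converts to/from the 1-based
inclusive external convention. Only CDS rows are modelled — every screen
operates on annotated protein-coding genes — and non-CDS rows are counted
and logged on read. Replicon kind (chromosome/plasmid) and topology, plus
genome-level metadata, ride in `#!merscape` pragma comments that other GFF3
consumers ignore; this makes `read ∘ write` the identity on the data model.
Circular topology is recorded but neighborhood scans do not wrap the
origin: the generator never plants origin-spanning operons, and real calls
abutting an origin would need a linearised annotation (a documented
limitation).

The isolation-source vocabulary is fixed (human, food, soil_sediment,
water, insect, other, unknown); unrecognised metadata values map to
`unknown` rather than failing a whole cohort load.

## Operon detection

Identification is lexicon-based: a CDS is *merA* when its gene name equals
`merA` (case-insensitive) or its product contains "mercuric reductase";
accessory genes match symbol-specific product phrases shipped as an
editable TSV (`merscape/data/mer_lexicon.tsv`). Keyword phrases are chosen
to avoid substring collisions (e.g. no bare `merC` keyword, which would hit
every "mercuric" product; no bare `merA`, which is a substring of
"polymerase").

From each anchor, candidates within ±`window_bp` (default 10,000 bp,
measured from the anchor CDS edges) are walked outward along the sorted CDS
list. Extension stops when

* the gap between directly adjacent CDSs exceeds `max_intergenic_gap_bp`
  (default 500 bp),
* a mer gene lies on the opposite strand — except *merR* immediately
  adjacent on the 5' side, since the regulator is commonly divergently
  transcribed (flag `allow_divergent_merR`, default on), or
* more than `max_embedded_nonmer` (default 1) consecutive non-mer CDSs
  would have to be skipped; skipped CDSs that end up between mer members
  are reported as `hyp` members.

All three knobs are parameters because the underlying field practice
("boundaries defined by synteny and functional annotation") is qualitative;
the defaults are declared, not inferred. Completeness requires *merR* and
*merA* plus at least one transport gene of *merT/P/C/F* (so *merF*
substitutes for *merC*); *merD/E/G* never affect completeness. Spectrum is
broad exactly when *merB* is a member. The architecture string lists
members 5'→3' on the operon strand, so mirroring a replicon leaves it
unchanged. Calls whose member sets intersect (two anchors in one cassette)
are merged.

Context annotation lists every MGE-category and MRG-category CDS within the
window but outside the span, with side (upstream/downstream on the operon
strand) and edge-to-edge distance (0 when abutting or overlapping).
Mercury-category genes are not listed as co-resident MRGs — they are the
operon system itself; other MRG subtypes map to czc/copper/chromate/
silver/arsenic, anything else to `other-metal`.

## Category lexicon and census

Categories are hierarchical (`ARG`, `MRG:<metal>`, `MGE:<element>`) and
matched by case-insensitive substring against gene name + product. Within
a top-level group one winner is kept, by priority then category name (a
"phage integrase" is one phage gene, not also an insertion gene); groups
are independent, so a "mercury resistance plasmid protein" is both an MRG
and an MGE. The default lexicon is a declared approximation of
annotation-database searches (ARG keywords cover beta-lactamase,
aminoglycoside, fluoroquinolone, phosphomycin, macrolide-efflux products);
it ships as TSV and any lexicon can be substituted. The census provenance
field carries a lexicon checksum so identical lexicons provably yield
identical censuses.

z-scores standardise each category column with sample SD (ddof 1);
zero-variance columns map to all-zero (not NaN), and values are clipped to
±4 by default, with the clipped-entry count surfaced. Per-replicon
proportions are 100 × category count / CDS count per replicon; a replicon
with no CDSs reports 0 % with a warning rather than NaN.

## Statistics

All permutation machinery is implemented directly on numpy arrays; scipy
supplies rank transforms, tail probabilities and clustering linkage only.

* **Bray–Curtis**: Σ|x−y| / Σ(x+y) on raw counts by default (the pipeline
  makes no silent transformation; presence/absence or normalised inputs
  can simply be passed in). Two all-zero rows get distance 0. The triangle
  inequality is not asserted — it does not hold for this index.
* **PERMANOVA**: distance-form sums of squares
  (SS_total = n⁻¹ Σ_{i<j} d²ᵢⱼ, within-group analogues), pseudo-F with
  (g−1, n−g) degrees of freedom, one-factor free permutation of labels.
  When the number of distinct label arrangements is ≤ `exhaustive_limit`
  (default 10,000) all are enumerated and p is exact; otherwise p uses the
  (b+1)/(m+1) convention over `n_perm` sampled permutations (default
  10,000). Permuted statistics are compared with a 1e-10 tolerance so a
  degenerate geometry (all distances equal) yields p = 1 rather than
  float-noise artefacts.
* **Dispersion homogeneity**: samples are embedded by classical scaling;
  squared distance to the group centroid is the positive-axis part minus
  the imaginary-axis part, floored at 0 (the standard correction for
  non-Euclidean indices). Centroids, not spatial medians, are used — the
  simpler and declared choice. F is a one-way ANOVA on the distances; p
  permutes group labels over the fixed distances. All-identical points are
  reported as degenerate with p = 1.
* **Kruskal–Wallis / Dunn**: tie-corrected H with a chi-square tail; Dunn z
  from pooled mid-ranks with the tie-corrected variance, two-sided normal
  p, Bonferroni over all pairs (capped at 1). The pipeline runs post hoc
  comparisons only when the global test is significant at α.
* **Dual correlations**: Pearson and Spearman with t-approximation
  p-values; an association is reported only when both are below α. Exact
  permutation p-values are available behind a flag for n ≤ 10. Zero
  variance in either vector is flagged degenerate and never reported.
* **PCA** operates on the correlation structure (centered, unit sample SD;
  constant columns dropped with a warning); **PCoA** double-centers −½D²,
  returns coordinates on positive-eigenvalue axes and reports the negative
  eigenvalue mass instead of hiding it. Axis signs are fixed so each
  axis's largest-magnitude element is positive, making ordinations
  deterministic.
* **Hierarchical clustering** delegates agglomeration to scipy (average
  linkage by default; the linkage is recorded in output metadata) and
  serialises the dendrogram as Newick with merges at half the merge
  height, so ultrametric inputs reproduce their leaf-to-leaf distances.

## Phylogeny

Protein distances use the 20-state Jukes–Cantor correction
d = −(19/20)·ln(1 − 20p/19) with pairwise deletion of gap/`X` columns —
pairwise rather than global deletion so taxa padded for a missing protein
retain signal elsewhere. Saturated pairs (p ≥ 19/20) are set to a ceiling
(default 5.0 substitutions/site) and flagged. Neighbor joining is the
classical Q-criterion algorithm with the standard split branch lengths;
negative lengths are clipped to 0 and counted; ties break on the
lexicographically smallest pair of subtree labels (keyed by smallest leaf),
making output deterministic. Bootstrap resamples alignment columns with
replacement; replicates with a saturated or incomparable pair are skipped
and counted (warned above 1 %), and supports are percentages over used
replicates, attached to the full-data tree's bipartitions (a majority-rule
consensus topology is deliberately not substituted; outgroup rooting is a
view that never changes bipartitions).

## LAG thresholds

Prevalences are exact `Fraction`s, so the half-open intervals
[0.60, 1] → restrictive and [0.40, 0.60) → lax classify printed boundary
cases (59/100 vs 60/100) without floating-point leakage. "40–59 %" is
implemented as the half-open interval, so 59.9 % is lax — integer-percent
phrasing leaves sub-percent values ambiguous and this is the declared
resolution. The summary reports shared families both inside each
lifestyle's counts and as a separate shared count, since either bookkeeping
is defensible.

## Synthetic-data generator

The generator's defaults define the validation conditions: a 30-genome
cohort with 20 planted operons covering the canonical merR/TPCAB cassette
(broad-spectrum), the extended TPCAB+DE form, the *merF*-substituted
transport variant, an isolated *merA*, a *tniA/B/Q*-flanked cassette on a
plasmid, and a *czc*-adjacent cassette; one genome carries two operons on
different replicons, and a third of genomes are negative controls.
Intergenic gaps inside planted operons are 10–150 bp; context genes sit
200–2,000 bp from the operon ends, inside the 10 kb window — away from the
rule boundaries, which get dedicated unit tests instead. Scattered
ARG/MRG/MGE genes are planted at Poisson rates (MGE > MRG > ARG per
genome, echoing the relative abundances such screens report) and background
genes draw products from a neutral vocabulary verified to miss every
lexicon keyword, so census ground truth is exact by recount. Per-genome
random streams derive from `SeedSequence((seed, genome_index))`, making
cohorts byte-reproducible and order-independent.

Alignment simulation evolves gap-free protein sequences down a given tree
with Poisson substitution counts per site and uniform replacement over the
other 19 residues — exactly the model the JC correction inverts, which is
what makes the phylogeny recovery tests sharp. Family matrices draw each
family independently per genome at its lifestyle's prevalence.

What the generator does **not** emulate: real nucleotide sequence, indels,
annotation noise (mislabelled products), origin-spanning features, genome
rearrangements, or correlated gene content beyond the planted structure.
Passing tests therefore demonstrate that the algorithms implement their
stated rules exactly and behave correctly under the stated statistical
models — not that the default lexicons capture every real-world annotation
variant.

## Problem sizes and runtime choices

The shipped validation runs use a 30-genome cohort (~130 genes/genome),
10,000 PERMANOVA permutations (vectorised over permutations), 1,000
bootstrap replicates on 4-taxon alignments of 912 columns, and 1,000-run
null calibrations for type-I error and the dual-reporting rule; the whole
suite plus the acceptance script completes in well under a minute on one
CPU. The end-to-end pipeline default of 500 bootstrap replicates (vs
10,000 for focused phylogeny runs) keeps the run-all bundle quick; the
replicate count is a config knob.

## Known limitations

* Lexicon matching inherits the annotation's vocabulary; products with
  unusual phrasing are missed (the paperless alternative — sequence-level
  database search — is out of scope by design).
* Window scans do not wrap circular origins.
* PERMANOVA is one-factor with free permutation; no strata or multi-factor
  designs.
* Bootstrap supports assume the full-data topology as reference; a
  consensus-tree mode would require explicit majority-rule construction.
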