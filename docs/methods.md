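# Methods

This note documents the models, rules and numerical choices behind
`plastmark`, and what the synthetic-data validation does and does not show.

## Tree distance and ranking

A bipartition (split) of an unrooted tree is the pair of leaf sets induced
by removing an internal edge; it is nontrivial when both sides contain at
least two leaves.  Splits are stored canonically as the block containing
the lexicographically smallest leaf label, which makes the computation
independent of rooting: `unroot` provably leaves the split set unchanged,
and `rf_distance` is the cardinality of the symmetric difference of the two
split sets.  The normalized RF divides by the total number of nontrivial
splits in both trees.  This denominator equals 2(n−3) for two binary
n-leaf trees and remains well defined for polytomies; two star trees are
defined to have distance 0.

Before a gene tree is compared with the target tree, the target is pruned
to the gene's taxon set (suppressed degree-2 nodes have branch lengths
summed) and both trees are unrooted.  Genes sharing fewer than four leaves
with the target have no nontrivial splits in common scope; their nRF is
reported as undefined rather than 0 and such genes are excluded from the
ranking with a logged note.  Ranks are ascending in nRF with mean-rank
ties.

Tree containers and newick I/O are delegated to dendropy; split extraction
and RF/nRF are computed by this package and cross-checked in the test suite
against both a brute-force enumeration oracle and dendropy's independent
implementation.  Neighbor joining (used only as the built-in estimator for
synthetic panels; real analyses are expected to supply externally inferred
trees) is delegated to scikit-bio, with negative branch lengths clamped to
zero.  Distances feeding NJ are Jukes–Cantor corrected p-distances,
d = −(3/4)·ln(1 − 4p/3), with saturated or incomparable pairs capped at
d = 5 substitutions/site so the agglomeration stays finite.

## Divergence statistics

* **p-distance** — mismatches over pairwise-comparable sites; sites with a
  gap or missing state (N for nucleotide, X for amino acid) in either
  sequence are excluded (pairwise deletion).  The per-gene value is the
  median over all sequence pairs; the mean is reported alongside.
* **Parsimony-informative fraction** — proportion of columns with at least
  two states each present in at least two sequences; gaps and missing
  states do not count as states.
* **dN/dS** — Nei–Gojobori (1986) counting.  Synonymous site counts per
  codon are the fraction of the nine possible single-base changes that
  preserve the amino acid (changes to stop codons count as nonsynonymous),
  averaged between the two sequences.  Codons containing gaps, ambiguity
  characters or stop codons in either sequence are skipped pairwise.
  Multi-step codon differences are averaged over all minimal mutation
  paths, excluding paths through stop codons (falling back to all paths in
  the degenerate case where every path is blocked).  Proportions are
  Jukes–Cantor corrected; pN or pS ≥ 3/4 makes the corresponding rate
  infinite and is flagged in a status field rather than silently clamped.
  This counting estimator replaces maximum-likelihood pairwise estimation:
  it is deterministic, closed-form and verifiable against an exhaustive
  enumeration oracle, and the downstream analysis consumes ranks and signs,
  not absolute rate values.  The default genetic code is the
  bacterial/plastid table (NCBI table 11, identical in codon→amino-acid
  assignments to the standard code), configurable everywhere.
* **Sliding-window profile** — mean pairwise p-distance in windows of 30
  alignment columns (step 1 by default; only the width is scientifically
  meaningful, the step merely controls resolution for primer placement).  A
  trailing partial window is kept if it spans at least half the width.

## Regression and outlier rule

The nRF-vs-divergence fit is ordinary least squares (via statsmodels) with
the classical prediction interval ŷ(x₀) ± t₍α/2,n−2₎·s·√(1+1/n+(x₀−x̄)²/Sxx),
s² = RSS/(n−2).  The closed-form interval is cross-checked against
statsmodels' observation interval in the tests.  A gene is flagged as a
candidate marker iff its nRF is strictly below the lower bound at its own
predictor value; boundary points are not flagged.  The default predictor is
the median p-distance; dN, the parsimony-informative fraction and the
alignment length are selectable.  No multiple-testing correction is applied
to the Spearman correlation p-values, which are descriptive.  Spearman's
rho uses mean ranks; its two-sided p-value uses the t approximation
t = ρ·√((n−2)/(1−ρ²)) for n > 7 and exhaustive permutation below (exact
mode is available up to n = 10, where enumeration is still cheap).

The bootstrap check draws, per iteration, one gene-tree replicate and one
target-tree replicate uniformly with replacement (independent indices by
default; a paired-index mode exists) and reports the median nRF over the
draws with the full draw list.

## Family assembly rules

Gene names are canonicalized (lower case, whitespace collapsed), with CDS
features falling back from `/gene` to `/product` and nameless features
dropped.  A taxon carrying two or more copies of a gene has all its copies
removed; if any taxon is duplicated the whole family is excluded by default
(paralogs make poor markers), or only the offending members when
`drop_duplicated` is off.  A member annotated as more than one coding
segment (`join` locations) is treated as fragmented and removed — member
removal, not family exclusion, is the default for fragmentation.
Translation keeps the longest stop-free ORF across the three forward
frames, requiring ≥ 50 residues by default; an ATG start is not required,
matching ORF-finder behaviour on extracted CDS.  Occupancy below 90% of the
panel (configurable, or an absolute `min_taxa`) excludes the family.
Back-translation trims a trailing stop codon, expands each residue to its
source codon and each gap to `---`, and errors per taxon on length
mismatches.  Amino-acid alignment itself is an input (any external aligner);
synthetic data is generated gap-free and pre-aligned, so no aligner is
bundled.

## Primer design rules

Conserved windows are maximal runs of profile windows with p-distance below
a user threshold (there is no universal default for "conserved enough"; the
CLI exposes `--max-pdist`, default 0.35).  The degenerate consensus
includes, per column, every base at frequency ≥ 0.5, or failing that adds
bases in descending frequency (ties alphabetical) until the cumulative
frequency reaches 0.5; gaps are ignored and all-gap columns emit N.
Degeneracy is the product of per-position ambiguity-set sizes.  Amplicon
length is measured in alignment columns from the forward primer's 5' start
to the reverse primer's 5' start; the reverse primer is the IUPAC-aware
reverse complement of the downstream window's 3' end.  Melting temperature,
hairpin and dimer screening are out of scope.

## Synthetic data: what it emulates, and what it does not

The generator exists to exercise the pipeline end to end, not to be a
population-genetic simulator.

* **Species tree** — pure-birth (Yule) tree, leaves t1..tn, branch lengths
  rescaled to a mean root-to-tip depth of 0.4 substitutions/site.  Raw Yule
  trees routinely contain internal edges of ~10⁻⁴ substitutions/site that
  no finite alignment can resolve, which would make even a perfectly
  concordant gene's estimated tree differ from the target; since the
  intended target is a *well-supported* genome tree, internal edges are
  floored at 0.015 and the four shortest pinned to a graded "shallow split"
  spectrum (0.015, 0.02, 0.025, 0.03).  These shallow splits are the
  realistic hard part of the target topology: weakly divergent genes miss
  them, strongly divergent genes recover them.
* **Gene trees** — the species tree after n random nearest-neighbor
  interchanges.  For panel construction the moves are resampled until the
  result differs from the source by exactly one bipartition per move
  (RF = 2·n), so "three NNI moves" deterministically means three displaced
  splits; unconstrained moves frequently overlap or cancel, which makes the
  induced discordance a random variable and (because the resulting spread
  inflates the regression's residual sd) can push the 95% PI lower bound
  below zero, where no gene can ever be flagged.
* **Sequences** — JC69 or K80(κ) site-independent evolution along the
  tree, uniform root composition, gap-free.  Codon structure is
  phenomenological: an `omega < 1` request scales first/second codon
  position rates down rather than using a true codon model.  No indels, no
  among-site rate heterogeneity beyond the position multipliers, no
  base-composition bias, no incomplete lineage sorting (discordance is
  topological, not coalescent).
* **Default panel** — 30 genes, rate scalars log-spaced 0.035–1.2 (median
  p-distances ≈ 0.03–0.5, the range spanned by real plastid genes), 27
  genes three NNI moves from the species tree and 3 concordant genes placed
  at the 30/60/90% gradient quantiles, 1000 codons per gene, 15 taxa.  The
  concordant genes sit above the low-divergence noise zone: below roughly
  the 20th gradient percentile, NJ trees genuinely miss shallow splits,
  which is precisely what produces the negative nRF-vs-divergence
  correlation the screen relies on, but would also mask a concordant gene
  placed there (a single missed split already lifts its nRF above the PI
  lower bound given the residual-sd inflation contributed by the outliers
  themselves).

Consequently, passing validation shows that the statistics are implemented
correctly and that the screen recovers planted signal under controlled
discordance and divergence; it does not show robustness to alignment
error, indels, compositional heterogeneity, model misspecification or
coalescent gene-tree variation in real panels.

## Numerical and interface conventions

Coordinates are 0-based half-open internally; 1-based inclusive only in
GenBank I/O and human-facing reports.  All randomness flows through
numpy Generators seeded explicitly; per-gene streams are derived from the
panel seed so any gene regenerates independently, and every output file
header records tool version, configuration hash and seed (seeded re-runs
are byte-identical; output paths are excluded from the hash).  Undefined
quantities (nRF with <4 shared leaves, p-distance with no comparable
sites, saturated dN/dS) are NaN/flagged, never silently zero.  Degenerate
fits (constant predictor, fewer than three points) raise errors instead of
returning unusable intervals.
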