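# Methods

This note documents the models, parameter choices, and numerical conventions
behind `ecfcoev`, and what the synthetic-data tests do and do not establish
about real data.

## Retrieval

Profile-HMM hits (hmmscan per-domain tables; only that dialect is accepted,
other layouts are rejected with the offending line) are curated into ASDI
records.  The score threshold for keeping a hit is chosen on a ROC curve
over labeled training scores via `sklearn.metrics.roc_curve`: the operating
point maximizes Youden's J = TPR − FPR under the rule "keep iff
score ≥ t", with candidate thresholds restricted to observed scores so the
choice is finite and reproducible.  Among J ties the smallest threshold wins
— a recall-favoring convention.  Defaults are the calibrated operating
points of the three domain models: 0.4 bits (non-zinc-binding model),
14.2 bits (zinc-binding), 0.2 bits (extended family model).

The domain interval is the envelope of the highest-scoring hit (ties break
to the smaller envelope start), minus any transmembrane/extracellular
segments; when the subtraction splits the envelope, the longest contiguous
remainder is kept (the handling of split envelopes is this package's
choice).  Domains shorter than 50 aa are removed (they are plausibly class
II anti-σ factors), exact duplicate domain sequences are collapsed to the
first occurrence, and each ASDI is paired with the nearest ECF within ±10
coding sequences by CDS ordinal distance, ties resolving downstream.

## Classification

Sequences are compared with an alignment-free k-tuple distance,
d(a,b) = 1 − S/(min(|a|,|b|) − k + 1), where S counts shared k-mers with
multiplicity; k defaults to 1.  This is a documented approximation of the
quick pairwise distances of progressive aligners, which do not publish a
closed formula.

Clustering is divisive: the largest-diameter cluster is repeatedly bisected
by a deterministic 2-medoid split (medoids initialized at the two most
distant members, assign/update iterated to convergence, ties to the lower
index) until every cluster's diameter — the maximum pairwise distance,
re-assertable post hoc — falls below τ = 0.6.  Medoid bisection on the
precomputed distance matrix replaces centroid K-means deliberately: it
needs no vector embedding of sequences and is deterministic under the
stated initialization.  Size-1 terminal clusters are emitted as
"ungrouped".  Subgroups that pass the HMM threshold but carry Pfam domains
incompatible with anti-σ function can be removed with a user-supplied
domain blacklist; no hardcoded rule is applied.

Consensus sequences drop columns with ≥ 50% gaps and otherwise take the
most frequent residue with an alphabetical tie-break (both conventions are
this package's choice).  The subgroup tree is neighbor joining on the
k-tuple distances of the consensus sequences (negative branch lengths
clamped to zero), rooted on the branch of a class II anti-σ outgroup;
an externally inferred maximum-likelihood tree can be supplied instead, in
which case only rooting is performed.  AS groups are the maximal
monophyletic clades whose leaves share one cognate ECF group, named
AS<number> after that group, with -1/-2 suffixes in preorder when one ECF
group occupies several clades.

Zinc-binding status is the presence of the 8-residue H-x3-C-x2-C signature,
optionally restricted to a window (the helix 2–3 region when alignment
annotation provides one; otherwise the whole domain is scanned, since the
helix boundaries are not well defined in unaligned coordinates).
Transmembrane topology and Pfam architecture are ingested, not predicted:
the TMH mode per subgroup ties to the smaller count, and conserved domains
require strictly more than half of the members.

## Mirror-tree coevolution

Family distances are fractional mismatches over mutually ungapped columns
(pairs with no comparable column are an error).  One protein per organism
is enforced; when several map to the same organism the first by protein-id
sort is used.  The statistic is the Pearson correlation of the two
upper-triangle distance vectors.  Significance is by exceedance: the
interacting pair is flagged significant iff its PCC strictly exceeds every
PCC involving a control family.  No parametric p-value is attached — the
distance pairs are phylogenetically dependent, and the exceedance rule is
the appropriate non-parametric reading of the control design.

## Gaussian DCA

The concatenated paired alignment (ECF columns 1..B, ASDI columns B+1..N,
alphabet of 20 residues + gap, q = 21) is modeled as a multivariate
Gaussian over one-hot-encoded columns.

- Reweighting: w_m = 1/|{m′ : d_H(m,m′)/N < θ}| with θ = 0.46 by default
  (the recorded run value for the real families); θ = "auto" uses the mean
  normalized Hamming distance, documented as an approximation of the
  original auto-tuning.
- Frequencies: pseudocount blend toward uniform, f_i(a) = (1−α)f̂_i(a)+α/q
  and f_ij(a,b) = (1−α)f̂_ij(a,b)+α/q² for i ≠ j, with
  f_ii(a,b) = δ_ab f_i(a); α defaults to 0.8, the cited Gaussian-DCA
  default.  The gap state is not stored; its mass is the remainder.
- Couplings: J = −C⁻¹ with C = f_ij − f_i f_j assembled over q−1 = 20
  states per column.  Dropping the gap state before inversion is a standard
  conditioning choice; C is positive definite for α > 0, and a singular C
  (α = 0 with degenerate data) raises an error advising a larger α.
- Scores: each block J_ij is shifted to the zero-sum gauge before taking
  its Frobenius norm F_ij; the average product correction subtracts
  F̄_i F̄_j / F̄ with means over off-diagonal entries.
- Contact extraction filters inter-protein pairs, sorts by score with a
  lexicographic column tie-break, truncates by `top_n` and/or a score
  cutoff (both exposed because the sensible truncation depth is
  data-dependent), and maps columns to the reference pair's 1-based residue
  numbering.  Columns gapped in the reference are reported unmapped and
  skipped by structure validation, which works in reference coordinates
  throughout.  An optional maximum-gap-fraction column mask (off by
  default) excludes gap-heavy columns from ranking.

The implementation is cross-checked in the tests against an independent
straight-line reimplementation (explicit loops, generic inversion) to
1e−8 on small alignments, and obeys row-duplication invariance and
column-permutation equivariance.

## Structure validation

PDB parsing uses ATOM records of the first model; disordered atoms resolve
to the highest-occupancy altloc, and residues with insertion codes are
skipped with a warning (the reference maps this pipeline consumes do not
address them).  Structure-to-reference residue maps are explicit TSV inputs.
A prediction is a "true interaction" when its Cα distance is below 15 Å in
a strict majority of the structures where both residues are mapped —
"strict majority of assessable structures" is this package's reading of
"most of the structures" when some residues are unmapped; predictions
mapped nowhere are "unassessable".  Per-structure contact sets are either
ingested from an external Voronoi tessellation run (the reference method)
or recomputed with a heavy-atom ≤ 5 Å surrogate that reports itself as
such.  Common contacts are the intersection across all structures, and the
crosscheck annotates each with the matching prediction rank, if any.  The
packaged 25-row common-contact table ships with the package as a fixture.

## SDP analysis

For each pair of groups with ≥ 100 members (configurable), columns are
ranked by the Jensen–Shannon divergence (base 2) between the two groups'
residue distributions with a 0.5-per-state pseudocount and the gap as a
21st state; zero-divergence columns are excluded and ties break by column
index.  JSD is a surrogate for the multiple-correspondence-analysis
statistic of the reference SDP tool, which is why externally computed rank
lists can be ingested and aggregated identically.  Aggregation is the
sum-of-inverse-ranks across all runs involving a group; the top-scoring
position per group is its SDP, ties to the smallest column.  Groups whose
mean gap fraction exceeds 0.5 fit the shared alignment poorly and trigger a
warning rather than removal.  Per-group selections are reported, plus their
distinct-position union.

## Synthetic data

The generator produces what the analyses assume, with full ground truth:

- Trees: Yule pure-birth, rescaled to unit root-to-tip height, so the
  substitution rate μ is the expected substitutions per site over a
  root-to-tip path.  μ defaults to 0.5, giving deep but unsaturated
  divergence comparable to a broad protein family.
- Substitution: per-site Poisson events with uniform replacement over the
  19 other residues; no indels, so rows are trivially aligned (an
  assumption, not a feature of real families).
- Coupling: when a planted column substitutes to residue a, its partner is
  set to φ(a) with probability ρ; φ is an involution swapping charge
  partners (D↔R, E↔K) and fixing everything else, mimicking the charged
  and hydrophobic-identity contact types at real interfaces.  Within a
  branch the ASDI sites mutate before the ECF sites, so ECF-driven
  overwrites win simultaneous-mutation conflicts.  Coupling requires a
  shared tree; `independent_trees` therefore excludes planted pairs.
- Groups: organism rows are split across groups, each with its own tree and
  a root drawn from a disjoint residue alphabet (round-robin partition of
  the 20 residues), giving clades distinct consensus compositions — the
  property the diameter-bounded clustering keys on.
- Zinc motifs: round(zinc_fraction · n_groups) group roots carry
  H-x3-C-x2-C at ASDI positions 11/15/18 with the three anchors protected
  from substitution.
- A separate helper plants one specificity-determining column per group on
  a shared noisy background for SDP recovery tests.

What passing these tests shows: the statistics recover planted signal under
the generator's idealized conditions (perfect alignment, uniform rates, no
indels, clean pairing).  What they do not show: robustness to alignment
error, heterotachy, paralog mispairing, or compositional bias — all present
in real families and outside this generator's scope.

## Problem sizes and numerics

The heavy checks run at M = 2000 rows × N = 100 columns for planted-contact
recovery (null calibration at M = 500 over 20 seeds, where the inversion
cost, which depends on N alone, dominates anyway), 100 replicate pairs at 60
taxa for mirror-tree separation, and 50 replicates of 12 groups × 100 rows
for SDP recovery — sizes chosen so the whole suite completes in about a
minute while leaving the stochastic margins wide.  Determinism: all
randomness flows from explicit seeds; the clustering, NJ, ranking, and
consensus operations carry documented tie-breaks (lower index, alphabetical,
lexicographic column order) so results are reproducible bit-for-bit.
Degenerate inputs fail loudly: all-one-class ROC labels, fully excluded
envelopes, zero-variance distance vectors, zero-overlap row pairs, singular
covariances, absent outgroups, and unlabeled leaves each raise a specific
error.

## Known limitations

- The k-tuple metric at k = 1 is compositional; closely related but
  rearranged sequences look similar to it.  Larger k is available via
  `DistanceParams(k=...)`.
- Internal NJ is a fallback for reproducibility; for publication-grade
  trees an external maximum-likelihood tree should be supplied and will be
  rooted in place.
- The heavy-atom contact surrogate is not a tessellation; ingested
  tessellation output takes precedence when available.
- Real-data census numbers (family counts, zinc fractions) require the
  external sequence set and supplementary table; the package recomputes
  them from such a table when one is supplied but ships none.
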