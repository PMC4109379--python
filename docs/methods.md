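# Methods

This note documents the statistical models, the numerical choices and the
assumptions behind `famgut`, in the spirit of a methods appendix: what each
procedure computes, which knobs matter, what the synthetic generator does
and does not emulate, and the design decisions that were genuinely open.

## Diversity and community structure

**Inverse Simpson.** Two estimators are provided. The default, the
unbiased form `D = N(N−1) / Σ nᵢ(nᵢ−1)`, matches the convention of the
mothur toolchain most 16S workflows use; the maximum-likelihood plug-in
`1/Σ pᵢ²` is available for textbook comparisons. The two agree as depth
grows (checked at N = 10⁵ on a uniform 10-taxon community, relative gap
< 1%). The unbiased denominator vanishes when every observed taxon is a
singleton; that degenerate case returns observed richness with a warning
rather than failing, since it occurs only at absurdly shallow depths.

**Yue–Clayton θ.** `θ = Σaᵢbᵢ / (Σ(aᵢ−bᵢ)² + Σaᵢbᵢ)` on relative
abundances; we report the dissimilarity `1 − θ`, which is 0 exactly for
identical compositions and 1 exactly for disjoint supports. A community
with zero total counts is treated as invalid input (error), not as
maximally distant: a zero community is an upstream filtering bug, not a
biological observation.

**Rarefaction.** Exact without-replacement subsampling
(`multivariate_hypergeometric`) to a fixed depth; samples shallower than
the depth are dropped with a warning (keeping them would reintroduce the
depth artifacts rarefaction exists to remove). Draws are made in a
canonical sorted feature order so results are invariant to the column
order of the input table. Defaults: 1,827 reads for 16S tables and
1,207,904 for metagenome-derived tables, the depths appropriate to the
target study design; both are plain parameters. Whether metagenome tables
are rarefied by read or by mapped-gene count is left to the caller — the
functions rarefy whatever count table they are given.

**Distance matrices and diversity reports** average over `iters`
independent rarefied draws (default 100). Single-draw analysis is
available via `iters=1`; averaging reduces the Monte-Carlo spread of each
entry roughly like 1/√iters (property-tested).

## Core microbiota

The rule is: relative abundance **strictly greater than** the abundance
floor (default 0.0005, i.e. 0.05%) in **at least** the prevalence
fraction (default 0.95) of an individual's samples, with the prevalence
comparison made on the exact fraction (no integer pre-rounding of
0.95 × n). Prevalence is computed on rarefied relative abundances,
matching the pipeline order (rarefy once, then analyze). Note that at
depth 1,827 the smallest nonzero abundance is 1/1827 ≈ 0.000547, so the
0.05% floor is equivalent to "at least one read" at that depth.

Group cores are intersections of member cores. The cohort core treats a
member as "having" a feature when the abundance rule passes in all of
that member's samples (with one sample per member, the per-sample rule);
a flag switches the floor to bare presence, since either reading is
defensible for a cross-sectional cohort. Members whose samples were all
dropped upstream (e.g. below the rarefaction depth) are excluded with a
warning. Coverage is `100 × (core counts) / (total counts)` pooled over
the scope's samples.

## Temporal stability and group contrasts

Within-subject similarity (`1 − θ_YC`) is grouped by exact day lag
(binning is available for sparse designs). The lag-trend slope is the OLS
fit of per-lag mean similarity on lag, but its confidence interval is
**permutation-based** (resampling the subject's day labels and re-deriving
the slope; basic interval from the 2.5/97.5 permutation percentiles). The
naive OLS interval is also offered but under-covers badly — lag-mean
points share samples, so their errors are dependent; under an
exchangeable-days null the permutation interval is exact. This was
verified on iid Dirichlet-multinomial subjects (19/20 seeds cover zero,
vs 12/20 for naive OLS).

Group contrasts use one number per individual — the mean similarity of
that individual's samples to the target group's samples (its own samples
excluded) — never pooled sample pairs, which would pseudo-replicate.
Contrasts between independent groups use the exact Wilcoxon rank-sum
test; the child–mother vs child–father contrast is paired within child
and uses the exact signed-rank test.

**Exact tests.** The permutation nulls are enumerated completely — all
C(n+m, n) group labelings for the rank-sum, all 2ⁿ sign assignments for
the signed-rank — via a subset-sum dynamic program over doubled midranks,
which is mathematically identical to explicit enumeration and handles
ties exactly. Two-sided p is `min(1, 2·min(lower tail, upper tail))`.
Zero differences are dropped; an all-zero pairing degenerates to p = 1
with a warning. Normal approximations with continuity correction
(via scipy) are available for large samples. Against tie-free inputs the
exact p-values match scipy's exact implementations to 1e-12, and
simulated type-I error at α = 0.05 sits at the attainable level of the
discrete null (≈ 0.0497 for n = 14 vs 14; ≈ 0.0488 for n = 10 pairs).

## Classification

Random forests (scikit-learn) with out-of-bag error as the headline
metric and Gini (mean decrease in impurity) importances, ranked with
deterministic tie-breaking by feature id. Default 10,000 trees (tests use
a few hundred for speed — the OOB estimate is already stable well below
that). Inputs are rarefied relative abundances by default; the top-k
refit (default k = 15) retrains on the highest-ranked features and
reports both the new OOB error and the subset. Misclassification is
reported per sample and per subject (count of misclassified samples per
true class). Fits are bit-reproducible under a fixed seed.

## Ordination and concordance

NMDS minimizes Kruskal stress-1 by SMACOF with monotone regression
(scikit-learn), best of 20 random restarts, tolerance 1e-6, max 500
iterations. Coordinates are not canonicalized for rotation or sign —
NMDS is rotation-invariant, so all tests compare distances, never raw
coordinates. `nmds_scan` chains dimensions, additionally seeding each
dimension with the best lower-dimensional solution padded by a zero
coordinate; since padding leaves embedded distances unchanged, reported
stress is non-increasing in dimension by construction rather than by
optimizer luck. A matrix whose off-diagonal entries are all equal carries
no rank information and is flagged degenerate.

Concordance defaults to the Mantel test with Pearson correlation of the
vectorized off-diagonal entries and a one-sided upper permutation p,
`(1 + #{r_perm ≥ r_obs}) / (1 + n_perm)`, permuting rows and columns of
the second matrix jointly (999 permutations by default); Spearman is a
flag. Procrustes correlation of two NMDS embeddings (`r = √(1 − m²)`) is
offered as an alternative concordance statistic, since for this family of
questions either is a reasonable reading and the two generally agree in
direction.

## Operational protein families

Score-to-distance conversion: for each unordered ORF pair with at least
one directed alignment hit, the symmetrized score is the mean of the
available directed bitscores, and `d = 1 − s̄ / min(selfₐ, self_b)`,
clamped to [0, 1] (clamping events are logged). Normalizing by the
smaller self-score keeps d(a, a) = 0 and bounds d ≤ 1 for meaningful
scores. The conversion is deliberately pluggable — the literature is not
unanimous about symmetrization — and the rule used is recorded in the
output provenance.

Clustering is agglomerative average linkage over the sparse distance set,
with pairs absent from the input contributing the saturating distance 1
to every linkage average (the behaviour of sparse average-neighbor
clustering with a "large" placeholder). Merging continues while the
smallest average linkage is ≤ the cutoff (default 0.25). Ties on the
merge distance are broken by the lexicographically smallest member id of
the candidate pair, making the partition deterministic and independent of
input pair order. Average linkage is monotone, so this greedy cut equals
cutting the full dendrogram at the cutoff; the implementation is verified
against scipy's dense average-linkage dendrogram on hundreds of random
instances, including sparse ones.

Sharing fractions: features (or OPF clusters) detected in every member of
a group, over features detected in any member; for clusters, detection in
a subject means at least one member ORF originates from that subject.

## The synthetic family generator

The generator emulates the statistical structure the analyses assume,
with full ground truth, so every downstream method can be validated
against planted answers.

**Noise model.** Dirichlet-multinomial: each subject has a fixed base
composition; each day draws a composition from
Dirichlet(base × concentration) and counts from a multinomial at a
lognormal depth. DM overdispersion is the standard parametric noise model
for microbiome counts; real data add compositional trends, measurement
batch effects and taxon-taxon dynamics that this model deliberately omits
(see limitations).

**Household structure (defaults).** Eight subjects, 26 daily samples
each: an exclusively breastfed infant, a partially weaned toddler, four
weaned children, two parents.

* A planted family core of 12 OTUs with expected mass 0.40 per non-infant
  member. Within-core proportions are subject-specific Dirichlet draws
  (α = 25 per feature); the weaned children's core proportions cluster
  around a shared sibling template (coupling concentration 150), so
  children resemble each other more than they resemble their parents.
  The core evenness α = 25 is chosen so the *smallest* planted core OTU
  stays safely above the 0.05% detection floor on almost every day even
  in the toddler, whose core mass is diluted by the infant-like mixture —
  a requirement for the planted core to be exactly recoverable, which is
  part of the generator's contract.
* 15 personal OTUs per subject (mass 0.35), which is what makes members
  machine-separable, as in real families.
* A 40-OTU shared environmental pool (mass 0.25), each subject including
  each pool OTU with probability 0.5 — with the guarantee that every pool
  OTU is absent from at least one non-infant member, so no environmental
  taxon can masquerade as family core.
* The infant is dominated by two taxa in a two-state switching regime
  (dominant mass 0.65, secondary 0.10, daily flip probability 0.2), with
  family-core taxa at only 3% total mass and two stable low-abundance
  background taxa — reproducing the small infant core and its low
  family-core coverage.
* The toddler's base is λ·infant + (1−λ)·weaned-style, λ = 0.4.
* Depths are lognormal with mean 5,000 (σ = 0.3), so rarefying to 1,827
  drops almost nothing. Concentration defaults to 300, giving
  within-subject day-to-day θ_YC similarity around 0.8.

**Community cohort.** One sample per member (155 members by default),
built from 4 planted common OTUs (mass 0.20; by default 3 of them reuse
family-core ids), a 100-OTU population pool (inclusion probability 0.7,
mass 0.50) and 8 personal OTUs (mass 0.30). These masses were set so that
cohort members are roughly as similar to each other as family members are
to one another, the structure the analyses are meant to probe.

**Functional tables.** KO-like (200 features, 66% universal) and OPF-like
(400 features, 7.3% universal) tables at three timepoints per subject,
sharing sample ids with the 16S table. Subject signatures over
present features are blended with a single global profile by an
`association` parameter: 0 gives one global profile (no concordance
signal), 1 reproduces the taxonomic counts exactly in the functional
namespace (so distance matrices coincide and Mantel r = 1), and the
default 0.8 yields Mantel r against taxonomy around 0.5–0.7. The pairwise
bitscore set plants protein families whose within-family distances are
uniform on [0.05, 0.20] (below the 0.25 cutoff) and whose cross-family
hits, when present (probability 0.1), land on [0.35, 0.70]; 10% of
families are "universal", carrying one ORF per subject. Recovery of the
planted partition by average-neighbor at 0.25 is therefore exact, by
construction.

**What passing tests do and do not show.** Recovery of planted structure
demonstrates the correctness of the estimators and the pipeline plumbing
under the stated noise model. It does not demonstrate robustness to
compositional drift, uneven taxon detection limits, chimeras/contamination
or true temporal autocorrelation — none of which the generator simulates.
The generator's defaults define one reference condition; they are not fit
to any dataset.

## Pipeline and reproducibility

The `run-all` pipeline derives one child seed per stage from the run seed
via `SeedSequence.spawn`, records the seed and a SHA-256 hash of the
canonical config JSON in every manifest, writes only plain-text artifacts
(TSV/JSON, phylip matrices, a mothur list file), and is byte-identical
across reruns with the same config and seed (no timestamps are written).
A stage failure aborts with the stage name; partial outputs are kept next
to a `FAILED` marker.

Problem sizes used by the test suite and the acceptance script — e.g.
100 subsampling iterations for 16S distances, 25 for functional
distances, 10,000 trees in the pipeline default but a few hundred in unit
tests, a 155-member cohort in the default run and 20–40 members in unit
tests — were chosen as the smallest sizes at which the quantities of
interest are stable; all are configuration parameters.

## Known limitations

* θ_YC is the only beta-diversity metric implemented; Bray–Curtis and
  UniFrac are out of scope (an extension point exists via
  `DistanceMatrix`).
* No variance estimator for θ_YC is provided; uncertainty is handled by
  subsample averaging and permutation procedures.
* The OPF stage consumes precomputed alignment scores; it does not run
  alignments, and KO assignment is consumed as a count table, never
  computed.
* The average-neighbor implementation is O(n³) in the number of ORFs —
  appropriate for the tens-to-thousands scale of the synthetic and test
  workloads, not for millions of ORFs.
* The exact Wilcoxon tests enumerate nulls cheaply up to a few dozen
  observations; beyond that the normal approximation should be used.
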