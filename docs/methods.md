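# Methods

## The model

`peddrugsafe` estimates a pediatric drug-safety profile from
encounter-level EMR event data in four stages.

### Pair universe and enrichment

Within each inpatient encounter, the distinct drugs are crossed with the
distinct diagnosis codes; every (drug, diagnosis) combination is one
association pair. Repeated administrations of a drug within one encounter
are collapsed first — without deduplication the pair universe would
depend on dosing-record granularity rather than on co-occurrence. The
universe is the multiset of all such pairs:
N = Σ over encounters of |drugs| × |diagnoses|, K = pairs involving the
drug, n = pairs involving the diagnosis, k = pairs matching both, so that
Σ K = Σ n = Σ k = N holds by construction.

For each observed pair the one-sided upper-tail hypergeometric
probability P(X ≥ k), with X ~ Hypergeom(N, K, n), measures
over-representation. The tail is computed as the survival function at
k − 1, avoiding the catastrophic cancellation of 1 − CDF for extreme k.
One-sided testing is deliberate: a drug–indication association is an
enrichment question; under-representation is not of interest.

The tested family is the set of pairs with k ≥ 1 — cells never observed
are not hypotheses. Bonferroni correction (p_adj = min(1, m·p_raw)) over
that family controls the family-wise error rate; p_adj < α (default 0.05)
flags a significant association. A `family="all"` option divides by every
drug × diagnosis cell instead for users who prefer the maximally
conservative family. The model is a conditional-independence null given
the margins; encounters contribute blocks of correlated pairs (one drug
co-occurs with all diagnoses of its encounter), which the hypergeometric
null ignores. Bonferroni's conservatism absorbs this in practice — the
null-simulation test keeps the empirical FWER within the binomial
envelope of α — but the p-values should be read as enrichment scores, not
calibrated per-pair probabilities.

### Drug distances and clustering

The significant associations, binarized, give each drug a diagnosis set;
drugs are compared by Jaccard distance (1 − intersection/union). Two
empty sets get distance 0: this convention is chosen so that drugs with
no significant association are mutually identical and maximally far from
every associated drug, which makes them collect into a single
"no-association" cluster — the structural analogue of the leftover
cluster every real cohort produces. With this convention the distance
remains a metric (verified by the triangle-inequality property test).

k-means partitions the drugs using each drug's row of the distance matrix
as its feature vector — the standard embedding of a precomputed distance
matrix for a centroid method; a PAM (k-medoids) alternative on the raw
distances is available via `method="pam"`. The cluster count k is chosen
by cluster-wise bootstrap stability: cluster the full data (reference),
then for each of B resamples of drugs with replacement, re-cluster the
resampled submatrix and score each reference cluster by its best Jaccard
membership overlap with any resample cluster, membership restricted to
the distinct drugs present in the resample. The mean over clusters and
resamples is the stability of k; the candidate k with the highest mean
wins, smallest k on ties (parsimony). Defaults: candidate range 10–50,
B = 100 resamples, 10 k-means restarts; all reducible for small cohorts.
Per-stage randomness is derived from one pipeline seed by stable hashing
of (seed, stage name), so any stage can be rerun in isolation and
identical configurations give identical outputs.

Each cluster's kernel diagnosis set contains the diagnoses significantly
associated with at least a `kernel_min_share` fraction of its member
drugs; the default 0 gives the union over members (1 gives the
intersection). Clusters are themselves hierarchically clustered
(average-linkage agglomeration, selectable) on the Jaccard distances
between kernel sets, and the drugs are embedded in 2-D by classical
multidimensional scaling — the top two eigenvectors of the
double-centered squared-distance matrix, scaled by the square roots of
their eigenvalues, with signs fixed so the largest-magnitude loading on
each axis is positive (deterministic output). SMACOF-style iterative MDS
was rejected because it is initialization-dependent.

### Safety levels

The 0–5 scale encodes the youngest pediatric population a drug's labeling
covers (5 preterm, 4 full-term newborn 0–28 days, 3 infant/toddler
>28 days–23 months, 2 child 2–11 years or pediatric indication without an
age, 1 adolescent 12–18 years, 0 none/not established/contraindicated).
When a numeric minimum labeled age is available it is binned to the scale
(negative ages are read as gestational, i.e. preterm; ages above 18 years
map to level 0 with a warning); a range like "6 to 17 years" contributes
its minimum. Across multiple indications, the minimum age is used. A
contraindication or a "safety not established" statement dominates any
age range — level 0 regardless. Drugs customarily assumed safe without
labeling (traditional formulations, external-use preparations) are still
level 0; their provenance tag preserves the distinction so the two
subgroups of level 0 can be reported separately.

Cluster-level safety is the arithmetic mean of member levels with the
sample (n−1) standard deviation, SD 0 for singletons, plus the per-level
count/proportion distribution. The size-weighted mean of cluster means
always equals the grand mean over drugs (conservation property test).

### Cohort comparison

Two cohorts' association datasets are aligned by diagnosis (one row per
diagnosis in the union: presence flags, per-mille incidence
1000 × carrying encounters / total encounters, counts of significantly
associated drugs per cohort and their overlap) and symmetrically by drug
(with use volume = deduplicated drug-event count). Alignment rows are
grouped by average-linkage agglomerative clustering on standardized
features — count-like columns are log1p-transformed then z-scored, flags
kept as 0/1 — cut at a configurable number of groups (defaults 7 diagnosis
groups, 4 drug groups). The exact feature set is an explicit design
choice, not a reconstruction of any particular study's preprocessing.
Group composition is profiled as percentages over a user-supplied
code-to-category map (ICD-10 chapter, ATC first level); unmapped codes
fall into an `unmapped` category.

## The synthetic generator

`simulate` emulates an inpatient EMR extract with latent clinical
conditions. Each encounter belongs to one of `n_blocks` blocks (uniform);
its diagnosis count and drug count are Poisson (defaults: mean 3
diagnoses and 6 drugs per encounter, a desk-scale inpatient-like load).
Each diagnosis slot draws from the encounter block's diagnosis pool,
except with probability `noise_prob` (default 0.1) uniformly from all
diagnoses; each drug slot draws from the block's drug pool with
probability `signal_prob`, else uniformly from all drugs. A pool of
`n_unassociated_drugs` appears only as background, exercising the
empty-set pathway. Label statements are drawn per drug from
`label_level_probs`; the default (0.43, 0.05, 0.30, 0.12, 0.05, 0.05)
over levels 0–5 yields a grand-mean level near 1.4, a labeling mix
typical of an inpatient pediatric formulary in which roughly 43% of drugs
lack usable pediatric labeling.

Three presets fix the study conditions used by the test suite: `strong`
(5 blocks, 100 drugs of which 10 unassociated, 150 diagnoses, 5,000
encounters, signal 0.95) is the primary recovery regression — the full
pipeline must select k = 5 or 6 (the unassociated pool may form its own
cluster) and match the planted blocks at adjusted Rand index ≥ 0.9 in at
least 8 of 10 seeds; `null` (signal 0, 50 drugs, 80 diagnoses, 2,000
encounters) calibrates the family-wise error rate over 200 replicates;
`weak` (signal 0.5) is for exploring the stability profile.

What the generator does **not** emulate: real ICD-10/ATC marginal
frequencies, age structure, seasonal admission patterns, per-patient
correlation across encounters, or graded (non-block) drug–diagnosis
effects. Passing tests therefore demonstrate correctness of the
statistics and recoverability of block-structured signal, not performance
on the messier association structure of real hospital data.

## Numerical and design notes

- Hypergeometric tails are exact to ≤1e-12 against direct pmf summation
  over all universes with N ≤ 20 (acceptance-level property test).
- k selection in the acceptance-scale recovery test uses B = 20 resamples
  and 10 restarts over k = 2..10; stability estimates at that problem
  size (100 drugs) are already near-deterministic for well-separated
  blocks, and the spec'd default B = 100 remains the production setting.
- Degenerate inputs: if no pair is significant, every diagnosis set is
  empty, all distances are 0 and no k is statistically distinguishable;
  the fitted model then places all drugs in one cluster instead of
  running model selection on an all-zero matrix. Calling `cluster_drugs`
  directly on data with fewer distinct rows than k warns
  (`DegenerateInputWarning`) and splits ties deterministically
  (lexicographic row order, round-robin) so the partition stays total.
- Ties in k selection go to the smallest k; k-means label ids are
  renumbered 1..k by order of first appearance so partitions compare
  stably across runs.
- Codes are whitespace-trimmed, case-preserved strings; ICD-10/ATC maps
  are optional side tables. Diagnosis codes are kept at full resolution;
  truncation to ICD-10 categories, if wanted, belongs to preprocessing.

## Known limitations

- The hypergeometric null ignores within-encounter pair correlation (see
  above); low-incidence diagnoses and rarely used drugs cannot reach
  significance under Bonferroni, so an absent association is not evidence
  of absence.
- Bootstrap stability rewards separation; for overlapping clusters it can
  prefer coarser k than the generative truth.
- The safety scale reflects labeling, not observed harm: a level-0 drug
  may be used safely off-label, and labeling practices differ across
  jurisdictions.
- Cohort-comparison groupings depend on the declared feature
  standardization; different choices give different (equally defensible)
  group boundaries.
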