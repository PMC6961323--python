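# peddrugsafe

Quantitative pediatric drug-safety profiling from electronic medical
records (EMRs).

Children are routinely treated with drugs whose labels say nothing about
pediatric use, and there has been no quantitative way to measure how safe
drug therapy is under a given clinical condition. `peddrugsafe` implements
a computational pipeline that turns encounter-level inpatient EMR data —
which drugs and which diagnosis codes were recorded in each encounter —
into:

1. **Significant drug–diagnosis associations.** Every drug and diagnosis
   recorded in the same encounter forms an association pair. For a pair
   observed *k* times, with *K* pairs involving the drug, *n* pairs
   involving the diagnosis and *N* pairs overall, the upper-tail
   hypergeometric probability P(X ≥ k) tests over-representation;
   Bonferroni-adjusted *P* < α (default 0.05) defines a significant
   association.
2. **Drug clusters under clinical conditions.** Each drug *dᵢ* is
   identified with its set of significantly associated diagnoses, and
   drugs are compared by Jaccard distance
   d_J(dᵢ, dⱼ) = 1 − |dᵢ ∩ dⱼ| / |dᵢ ∪ dⱼ|.
   k-means partitions the drugs (rows of the distance matrix as features),
   with the cluster count k chosen by bootstrap cluster stability (mean
   cluster-wise Jaccard index over resamples, candidate range 10–50 by
   default). Each cluster gets a kernel diagnosis set, an inter-cluster
   hierarchy, and 2-D classical-MDS coordinates.
3. **A 0–5 pediatric safety level per drug and per cluster.** The level is
   the youngest population covered by the drug's pediatric labeling:
   5 preterm newborns, 4 full-term newborns (0–28 days), 3 infants and
   toddlers (>28 days–23 months), 2 children (2–11 years, or a pediatric
   indication without an age), 1 adolescents (12–18 years), 0 no pediatric
   labeling / not established / contraindicated. Cluster safety is the
   mean member level ± sample SD — a quantitative safety measurement for
   the cluster's clinical condition.
4. **Two-cohort comparison.** Association datasets from two hospitals
   (e.g. a children's vs a general hospital) are aligned by diagnosis and
   by drug, with per-mille incidences, use volumes, association counts and
   overlaps, hierarchical grouping of the alignment rows, and per-group
   ICD-10/ATC composition — exposing the drug-treatment gap between
   populations.

Intended users are pharmacoepidemiologists and clinical informaticians
with access to encounter-level medication and diagnosis extracts. Since
real EMR extracts cannot be shared, the package also ships a synthetic
cohort generator with planted drug–diagnosis block structure so the whole
pipeline is testable and demonstrable end to end.

## Worked example

```python
import peddrugsafe as pds

# a synthetic children's-hospital-like cohort: 5 planted condition blocks,
# 40 drugs (5 never associated with any diagnosis), 60 diagnoses
cfg = pds.preset("strong", seed=11, n_encounters=1500, n_drugs=40,
                 n_diagnoses=60, n_unassociated_drugs=5)
encounters, truth = pds.generate_cohort(cfg)
labels = pds.generate_labels(cfg, truth)

model = pds.DrugSafetyModel(
    encounters, labels=labels,
    clustering=pds.ClusteringConfig(k_min=2, k_max=8, B=10),
)
results = model.fit(seed=5)
print(results.summary())
```

prints

```
Pediatric drug-safety profile
================================================================
Encounters: 1500    Drugs: 40    Diagnoses: 60
Drug-diagnosis pairs (N): 17098
Tested pairs (m): 1779    alpha: 0.05
Significant associations: 420

Clusters (k): 6
Bootstrap stability at k: 1.000
Cluster sizes: 1:7, 2:7, 3:7, 4:7, 5:7, 6:5

Per-cluster pediatric safety level (mean +/- sample SD):
 cluster_id  n_drugs  mean_level  sd_level
          1        7       1.143     1.574
          2        7       0.714     1.254
          3        7       1.429     1.512
          4        7       1.571     1.134
          5        7       0.571     0.976
          6        5       1.200     1.304
Overall: n=40 mean=1.10 sd=1.28
```

Reading this: the 1,500 encounters produced N = 17,098 drug–diagnosis
pairs, of which 1,779 distinct pairs were tested and 420 were significant
after Bonferroni correction — exactly the planted block pairs. Bootstrap
stability peaks at k = 6: the 5 planted condition clusters of 7 drugs each
plus the 5 never-associated drugs collecting into their own cluster
(empty diagnosis sets are mutually at Jaccard distance 0). The per-cluster
means are the quantitative safety levels of those conditions; comparing
the recovered partition with the planted truth gives an adjusted Rand
index of 1.0 (`pds.evaluate_recovery(results.clustering, truth)`).

`results.save("outdir")` writes every artifact (association table,
binary significance matrix, distance matrix, partition, stability profile,
kernel sets, Newick hierarchy, MDS coordinates, safety tables) as
delimited text plus a `manifest.json` with parameters, seed and input
checksums.

The same pipeline is scriptable from the shell:

```bash
peddrugsafe simulate --preset strong --seed 7 --out sim/
peddrugsafe run --medications sim/medications.tsv --diagnoses sim/diagnoses.tsv \
    --labels sim/labels.tsv --kmin 2 --kmax 10 --bootstrap 20 --seed 7 --out run/
```

with `enrich`, `distance`, `cluster`, `safety` and `compare` subcommands
for running stages in isolation on the intermediate files.

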