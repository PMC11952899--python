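# granulekit

Sequence-based prediction of RNA granule proteins and analysis of the
PPI "community grammar" of the predicted proteome.

RNA granules (stress granules, P-bodies and related membraneless
organelles) are assemblies of RNA and RNA-binding proteins. Their
protein composition is heterogeneous across stresses and experimental
methods, which makes catalogue-based study difficult. `granulekit`
addresses this with a machine-learning pipeline for computational
biologists working on phase separation and granule biology:

1. **Features** (`granulekit.seqfeat`) — each protein sequence becomes a
   139-dimensional vector: 19 physicochemical descriptors (length,
   molecular weight, isoelectric point, GRAVY, low-complexity-region
   fraction, charge and composition summaries, Vihinen flexibility, ...),
   20 amino-acid composition fractions, and occurrence fractions of the
   50 most abundant 2-mers and 50 most abundant 3-mers of the positive
   training set (capturing granule grammar such as RG/RGG/GRG motifs).
2. **Cohorts** (`granulekit.cohort`) — balanced learning sets from a
   tier-annotated granule catalogue (tier 1 = strongest evidence) and a
   background proteome, with all catalogued candidates excluded from the
   negative class.
3. **Classifier** (`granulekit.granulerf`) — a random forest
   (500 trees, √p features per split) with stratified 10-fold
   cross-validation, per-fold leakage-free k-mer vocabulary selection,
   averaged Gini importances, tier-wise identification rates,
   proteome-wide propensity tables (high-confidence cutoff p > 0.7), and
   Mann–Whitney/BH group-comparison statistics.
4. **Profiles** (`granulekit.profiler`) — per-residue propensity tracks
   from sliding windows, with probability-peak calling and windowed
   GRAVY / cysteine tracks.
5. **Network** (`granulekit.granulenet`) — the predicted-proteome PPI
   graph from a STRING-style edge list: seven centrality metrics with
   percentile ranks, probability-binned trends with adjacent-bin ANOVA,
   Louvain clusters with high-confidence summaries, multi-list overlap
   (Venn) counts, and a seeded 2D embedding for plotting.
6. **Synthetic data** (`granulekit.synthdata`) — generators for
   proteomes with planted granule-like signal (RGG insertions, GRAVY
   shift, low-complexity stretches, cysteine depletion, tier-decaying
   strength) and propensity-coupled stochastic-block-model PPI edge
   lists, so the whole pipeline is testable without downloads.

## Model

For protein *i* with feature vector *x_i*, a random forest estimates
the granule propensity *p_i = P(granule | x_i)* as the positive-class
vote fraction. Performance is summarized by ROC AUC and PR-AUC (mean ±
SEM over 10 folds). On the network side, node importance uses degree,
betweenness, eigenvector centrality, PageRank (damping 0.85), closeness
(Wasserman–Faust), clustering coefficient and degree centrality, each
also expressed as a mid-rank percentile in [0, 1]; communities are
Louvain modularity clusters relabeled by size.

## Worked example

Everything below runs on synthetic data generated by the package
itself:

```sh
granule simulate --seed 1 --n-positives 200 --n-background 400 --ppi-nodes 300 --out sim
granule cohort   --tiers sim/tiers.tsv --fasta sim/proteome.fa \
                 --type PBSG --tier-rule '==1' --seed 1 --out set.tsv
granule cv       --fasta sim/proteome.fa --set set.tsv --seed 1 --trees 300 --out cvres
granule train    --fasta sim/proteome.fa --set set.tsv --seed 1 --trees 300 --out model.joblib
granule predict  --model model.joblib --fasta sim/proteome.fa --out propensity.tsv
granule tier-rates --model model.joblib --fasta sim/proteome.fa \
                 --tiers sim/tiers.tsv --out rates.json
granule clusters --edges sim/ppi_edges.tsv --propensity sim/ppi_propensity.tsv \
                 --seed 1 --out clu
```

prints

```
synthetic inputs written to sim
50 positives + 50 negatives
AUC 1.000 +/- 0.000, PR-AUC 1.000 +/- 0.000
model saved to model.joblib
110 high-confidence predictions
tier 1: 100.0%, tier 2: 96.0%, tier 3: 64.0%, tier 4: 24.0%
3 clusters, modularity 0.570
```

Reading: the 50 tier-1 positives of the simulated catalogue plus 50
sampled background negatives are perfectly separable under 10-fold CV
(the planted compositional signal is strong at tier 1); identification
rates then decay with catalogue tier exactly as evidence strength
decays (100% → 24%); and Louvain recovers the three planted PPI blocks
of the simulated community. `propensity.tsv` holds one row per protein
with its propensity and high-confidence flag.

The same steps apply unchanged to real inputs: a UniProt FASTA
proteome, an RNAgranuleDB-style tier TSV, and a STRING edge list.

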