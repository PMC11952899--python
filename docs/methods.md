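# Methods

## Problem and model

`granulekit` treats RNA granule membership as a binary sequence
classification problem. Positives are catalogued granule proteins
(stress granule SG, P-body PB, or the union PBSG) at a chosen evidence
tier; negatives are background-proteome proteins outside the catalogue.
A random forest over a 139-column sequence representation estimates the
granule propensity p ∈ [0, 1] of every protein, and the predicted
proteome's protein–protein-interaction network is then analyzed for its
community structure.

The underlying assumptions: (i) granule propensity is encoded in
sequence composition — hydropathy, charge, low-complexity content and
short motifs (notably RG/RGG/GRG) — rather than in structure or
modifications; (ii) evidence tiers order signal strength, so weaker
tiers should be recovered at lower rates; (iii) high-propensity
proteins form dense PPI "cores", so node importance should rise with
propensity.

## Feature representation

* **19 physicochemical descriptors** — length; molecular weight;
  isoelectric point; GRAVY (mean Kyte–Doolittle hydropathy);
  low-complexity-region (LCR) fraction; aromaticity (F+W+Y); net charge
  at pH 7; K+R fraction; D+E fraction; charged fraction; charge
  asymmetry; polar fraction (S,T,N,Q,C,Y); tiny fraction (A,G,S); P, G,
  C and S fractions; mean Vihinen flexibility; maximal homopolymer run
  length / length. The list is a deliberate sequence-only span of the
  axes known to separate granule proteins (hydropathy, disorder,
  charge, cysteine content); it is held in one canonical tuple so it
  can be swapped without touching the callers.
* **20 amino-acid composition fractions** (sum to 1 per protein).
* **50 + 50 k-mer fractions** — the 2-mers and 3-mers with the highest
  total overlapping counts over the positive training set, ties broken
  alphabetically; the per-protein value is count / (L − k + 1).
  Normalizing by window count rather than by L keeps fractions in
  [0, 1] for all lengths.

Numerical choices: the isoelectric point solves net charge = 0 by
bisection on pH ∈ [0, 14] to |q| < 1e−6 under the EMBOSS pKa set
(N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5,
Y 10.1) — the charge model is strictly monotone in pH, so bisection
always converges. LCR detection slides a 12-residue window and flags
windows with Shannon entropy < 2.2 bits (SEG-like trigger values);
a residue is LCR if any flagged window covers it; sequences shorter
than the window are scored as one whole-sequence window. Non-canonical
residues are mapped U→C, B→D, Z→E and all others dropped by default
(`drop-residue` / `drop-protein` policies available).

## Cohorts

Negatives are drawn uniformly without replacement (seeded) from the
background proteome after excluding **every** catalogued accession of
any tier and any granule type, because weaker-tier candidates are later
scored as prediction targets and must not contaminate the negative
class. Learning sets are exactly balanced. PBSG positives are the union
of SG and PB at the stated tier rule. A single seeded negative draw is
used per learning set; repeated draws are supported via the seed.

## Classifier and evaluation

Random forest: 500 trees (defaults; tests and loops use smaller
forests), √p features per split, unlimited depth, seeded. Stratified
10-fold CV reports per-fold ROC AUC and PR-AUC (mean ± SEM, SEM =
sd/√10) and per-fold Gini importances. In strict mode (default) the
k-mer vocabulary is re-selected inside every training fold from that
fold's positives only, so vocabulary selection never sees held-out
proteins; fold importances are averaged by feature name over the union
of columns with absent-in-fold = 0, which preserves the unit sum. A
documented fast mode selects the vocabulary once.

Tier identification rate(t) = share of tier-t catalogue proteins with
p ≥ 0.5 (configurable); the high-confidence proteome uses p > 0.7.
Group comparisons (granule vs background features, k-mer enrichment
including the RG/RGG/GRG motif panel) use two-sided Mann–Whitney U
with Benjamini–Hochberg adjustment across the tested features; raw
p-values are also emitted. Mann–Whitney is preferred over the t-test
because sequence features are skewed.

## Profiles

Windows of 50 residues at step 5 (defaults; both configurable — 50
resolves ~80-residue RNA-binding domains while smoothing noise) are
featurized exactly as full proteins, so the length feature equals the
window length. A terminal stub is kept when ≥ window/2; sequences
shorter than window/2 get one whole-sequence window. The per-residue
track is the mean over covering windows (stabler than max); residues
past the last window inherit the final window's score so the track has
length L. Peaks are maximal runs of per-residue p ≥ 0.7 with length
≥ 10, annotated with the mean windowed GRAVY and cysteine fraction of
the overlapping windows.

## Network analysis

Edges with combined score ≥ 400 (STRING "medium confidence"; the
threshold is a parameter) form an undirected simple graph; weights are
used only for thresholding, and all metrics run unweighted. The seven
node metrics: degree; normalized betweenness; eigenvector centrality by
power iteration (tol 1e−8) per connected component, singletons 0;
PageRank (damping 0.85, tol 1e−9, uniform teleport); closeness with
the Wasserman–Faust component correction; local clustering coefficient;
degree centrality. Percentile ranks are mid-rank fractions (ties
averaged), so the unique maximum maps to 1.0 and ranks are invariant
under strictly monotone transforms.

Probability bins are [0.5,0.6), [0.6,0.7), [0.7,0.8), [0.8,0.9),
[0.9,1.0]; each bin is compared with its predecessor by one-way ANOVA
per metric (adjacent comparisons, not an omnibus test; raw p-values).
Bins with n < 2 are flagged and skipped; identical constant groups
report F = 0, p = 1.

Louvain clustering (networkx implementation, seeded, resolution 1.0)
relabels clusters 1, 2, ... by descending size with lexicographic
tie-break, making "cluster 1/2/3" reproducible for a given seed.
Cluster summaries report, per cluster, the high-confidence members
(p > 0.7), their count, mean propensity and mean PageRank percentile;
the top-3 clusters by high-confidence size are flagged. Multi-list
overlap analysis deduplicates each list and reports union size,
per-region Venn counts and the intersection of all lists. The 2D t-SNE
embedding of adjacency rows is seeded plotting plumbing with no
accuracy contract.

## Synthetic data

The generator emulates the statistical structure the method assumes,
not real proteome marginals. Background sequences draw i.i.d. residues
from a human-proteome-like composition table embedded as data,
exponentially tilted (f ∝ f₀·e^{β·kd}, β solved by bisection) so the
expected GRAVY is −0.2. Lengths are log-normal (median 400, σ = 0.5,
floor 50). Positives at signal strength d (tier decay 1.0/0.75/0.5/0.25
for tiers 1–4) additionally get: a GRAVY target shifted toward −0.6 by
fraction d; cysteine frequency scaled toward ×0.4; one 20–60-residue
low-entropy stretch (85/15 two-letter mix over polar residues) with
probability 0.8·d; and Poisson(L/100 · 1.5·d) RGG insertions. Motif
insertion and the LCR stretch shift realized GRAVY slightly below the
compositional target; the planted signals are deliberately compounding,
as in real granule proteins.

The PPI generator is a stochastic block model: nodes ranked by
propensity are split into equal contiguous blocks (densest block =
highest propensity), with edge probability = block base rate (p_in 0.3
within, p_out 0.01 between) × ((p_i·p_j)/0.75²)^γ. Coupling γ = 1 by
default makes expected degree increase with propensity; γ = 0 recovers
the plain SBM used for community-recovery benchmarks. Combined scores
are uniform integers in [400, 999].

What passing tests show — and do not: the pipeline recovers planted
compositional signal, ordered tier decay, planted communities and
propensity–degree coupling under i.i.d.-residue backgrounds. Real
proteomes have domain structure, homology redundancy, length–
composition dependence and annotation noise that the generator does not
model, so synthetic performance bounds nothing about real-data AUC.

## Problem sizes and determinism

Default benchmark sizes: 200+200 balanced learning sets for CV (400
positives across four tiers plus background for tier-rate runs), 180
nodes for SBM recovery, 600 nodes for the degree-trend benchmark;
repeated-seed checks use 10 seeds with smaller forests (150–200 trees).
Every stochastic step (generation, negative sampling, fold splitting,
forest, Louvain, t-SNE) takes an explicit seed, and same-seed runs are
bit-identical, including serialized models reloaded from disk.

## Known limitations

* The 19-descriptor list is a documented default, not a learned or
  canonical set; alternatives plug in behind the same tuple.
* LCR detection is an entropy-window approximation of SEG, not SEG.
* Composition fraction of C and the cysteine-fraction descriptor are
  duplicated representations; forests split importance between them.
* Real-data headline quantities (catalogue AUC, proteome-scale network
  size, cluster sizes) depend on external databases and are outside the
  test surface; the package exposes the identical code paths for them.
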