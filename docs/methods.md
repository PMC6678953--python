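# Methods

## Problem setting

A multiple-cause-of-death (MCOD) record lists every health condition
entered on a death certificate — up to 20 entity-axis ICD-10 codes —
besides the single underlying cause. `somward` clusters decedents by
the *set* of disease categories present at death and profiles the
resulting groups against the whole population. The pipeline is built
for data too large for direct hierarchical clustering (tens of millions
of records): a self-organizing map (SOM) compresses the record space
into ~10²–10³ node prototypes, hierarchical clustering runs on the
nodes, and every record inherits the cluster of its best-matching node.

## Coding and indicators

ICD-10 codes are aggregated to disease categories through an ordered
prefix-rule table (`CategoryMap`): the longest matching prefix wins and
equal-length prefixes resolve by rule order, so lookup is deterministic.
The full study-scale configuration would use several hundred categories;
the bundled demo map defines ~35 covering the major cardiovascular,
respiratory, neoplastic, neurodegenerative, metabolic, renal, hepatic
and external-cause groups, with an `other` fallback bucket. The map is
user-replaceable configuration, not code.

Per record: categories are deduplicated across entity codes (duplicate
codes in the same category count once — conditions, not codes, are the
unit), the multimorbidity flag is `1` iff ≥ 2 distinct categories
remain, and the underlying cause is mapped separately without being
force-added to the condition set. Records with no health condition are
omitted, with parsed / malformed / omitted / usable counts carried in
the run manifest. The record × category indicator matrix is binary and
unscaled; a per-column variance scaling exists behind a flag but is off
by default because the clustering features are already on a common
{0,1} scale.

Age bands default to <18, 18–40, 41–64, 65–84, ≥85 years and are
configurable.

## Batch SOM

* **Lattice** — rectangular, row-major indexing, Euclidean distance
  between integer node coordinates. (Hexagonal lattices are a common
  alternative; the rectangular choice keeps adjacency and plotting
  simple and changes nothing structurally.)
* **Initialization** — PCA-plane: codebooks laid out linearly on the
  span of the first two principal axes, one standard deviation each
  way, centered on the data mean; the longer grid axis follows the
  first principal axis. Zero-variance data degrade to a mean plane with
  a warning. A seeded random-row initialization is also available.
* **Update** — batch rule: every epoch assigns best-matching units
  (BMUs; squared-Euclidean argmin, ties to the lowest node index) for
  all sample rows, then replaces each codebook by the
  Gaussian-neighborhood weighted mean of the sample. The update is a
  convex combination of data rows, so codebooks remain inside the
  data's column ranges — inside [0,1] for indicator data. Nodes
  receiving zero kernel mass keep their previous vector. In the
  vanishing-radius limit one epoch is exactly one Lloyd (k-means)
  update, which the tests exploit as an oracle.
* **Schedule** — neighborhood radius σ interpolates linearly from
  `max(rows, cols)/2` to 0.5 over 30 epochs (defaults). With a single
  epoch the final radius is used.
* **Sampling** — training uses a seeded sample without replacement
  (default cap 200,000 rows; the benchmark configuration uses 20,000);
  BMU mapping afterwards always covers all records. A quantization
  error trace (mean record-to-BMU distance; one entry for the initial
  codebook plus one per epoch) is stored as a fit diagnostic.

## SOM-Ward clustering

Ward's minimum-variance agglomeration restricted to the map topology:
only clusters containing lattice-adjacent nodes (4-connectivity by
default) may merge. Merge cost is the exact increase in total
within-cluster sum of squares,
`Δ = w_a·w_b/(w_a+w_b)·‖μ_a−μ_b‖²`.

Design points:

* **Weights are mapped record counts**, not one per node — the analysis
  clusters people, and a node summarizing 10,000 records must cost more
  to move than one summarizing 12.
* **Empty nodes** are pre-attached with zero weight to their nearest
  non-empty node (ties to the lowest index), keeping regions connected
  without distorting any Ward cost.
* **Determinism** — minimal cost first; cost ties resolve by the
  lexicographically smallest pair of lowest member-node indices. Final
  labels are 0..k−1 by decreasing cluster weight.
* **Non-monotone merges** — under the adjacency constraint the accepted
  merge-cost sequence need not be monotone, so no such invariant is
  asserted. When the unconstrained-optimal merge is adjacent at every
  step (monotone 1-D layouts), constrained and unconstrained Ward
  coincide exactly; this is a test oracle.
* **Choice of k** — the bundled study-replication configuration fixes
  k = 16. The `choose_k` helper (largest relative jump in successive
  merge costs over k ∈ [2, 30], ties to the smallest k) is this
  package's own suggestion device, offered because hierarchical
  clustering tools usually provide one; a user-supplied k always wins.

### Restart selection

SOM training can settle into a map whose topological ordering splits one
data cluster across disconnected regions; the adjacency constraint then
forces a bad cut elsewhere. `SomWardModel.fit` therefore trains
`n_restarts` maps (default 3) from seeds derived deterministically from
the master seed and keeps the fit whose k-cluster partition attains the
lowest record-level within-cluster sum of squares — the Ward objective
itself. Quantization error cannot play this role: it measures vector
quantization, not topology, and in our experiments was uncorrelated
with cut quality while the Ward objective tracked it closely.

## Cluster profiling

* **Denominators.** Categorical attributes (sex, race, education,
  marital status, resident status, place and manner of death) are
  tabulated over records with a *known* level — the non-missing
  denominator. This convention is forced by the internal arithmetic of
  published mortality tables: the printed education, marital, place and
  manner percentages reproduce only when divided by the sum of the
  printed level counts, while sex, race and multimorbidity percentages
  reproduce over the full population. Binary condition indicators
  (category prevalence, multimorbidity) accordingly use the full
  cluster size.
* **Tests.** "Cluster mean versus global mean" is operationalised as a
  two-sided Welch two-sample t-test of the cluster against its
  complement, which is well-defined at every cluster size and does not
  double-count the cluster inside its own reference; a literal
  one-sample mode against the fixed global mean is provided as
  `mode="global_constant"`. Significance uses the a-priori threshold
  p < 0.01; no multiple-testing correction by default (an optional
  Bonferroni flag adjusts the threshold across all cluster-level tests).
  Categorical attributes are tested per level on the 0/1 indicator.
  Tests are flagged unavailable below two non-missing values per side,
  including the degenerate single-cluster case.
* **Rounding.** Half-up; two decimals in tables, one decimal in
  prose-style figures (e.g. comorbidity shares).
* **Rankings.** Top-5 conditions by share of cluster records carrying
  the category, and top-5 underlying causes by share with that
  underlying category; descending, ties alphabetical.

## Synthetic benchmark population

The generator is a latent-class model standing in for restricted
vital-statistics files: cluster membership is the only source of
dependence, and given the cluster every disease category is an
independent Bernoulli draw. Each of the 16 clusters has

* a **signature pair** of categories unique to it — the first at
  prevalence 0.99 (the cluster's defining condition is near-certain on
  the certificate), the second at 0.80 in chronic clusters and 0.30 in
  the sudden-death clusters (ischemic heart disease, stroke, the two
  cancer screening-detected groups, poisoning, open wound/suffocation);
* a shared background (cardiac arrest, ill-defined `other` codes) and a
  cluster-specific **comorbidity profile** — a window of five categories
  at elevated prevalence, rolled through the vocabulary so profiles
  differ between clusters — both multiplied by a per-cluster background
  scale. That scale is the dial separating chronic multi-condition
  deaths from sudden deaths with few accompanying conditions, and is
  what carries the multimorbidity margin;
* truncated-normal age (means 42–85 years by cluster, truncation to
  [0, 130]), categorical demographic distributions perturbed around the
  published whole-population margins, and an underlying cause drawn
  from the record's present categories with signature categories
  up-weighted ×5.

If a record draws no condition, the cluster's top category is forced so
every record is usable by construction (`allow_empty_fraction` disables
this for filter testing). Attribute missingness defaults to the rates
implied by the published margins (education 3.3%, marital 1.0%, place
0.5%, manner 19.1%).

Weights, prevalences and ages are calibrated so that a 100,000-record
draw reproduces the real data's gross margins — mean conditions per
record ≈ 2.9 (target band 2.8–3.3), multimorbidity ≈ 78% (75–82%), mean
age ≈ 72 (71–75) — while keeping the clusters well separated (disjoint
high-prevalence sets). Under these conditions the full pipeline at
k = 16 recovers the planted labels with adjusted Rand index ≈ 0.92–0.94
across seeds.

**What the generator does not emulate** — and therefore what passing
tests do not show about real data: real condition co-occurrence within
a patient (conditions are independent given the cluster, so no
comorbidity correlations beyond cluster membership), code-level detail
(one representative ICD-10 code per category), temporal trends across
data years, geographic structure, and the far weaker separation real
mortality clusters exhibit. Recovery of the planted structure validates
the pipeline's mechanics, not the discriminative power of SOM-Ward on
real certificates.

## Numerical choices and degenerate inputs

* BMU ties → lowest node index; Ward cost ties → smallest member-node
  pair; `choose_k` ties → smallest k; all for bitwise determinism.
* Merge-cost ratios with a zero denominator: 0/0 counts as 1, x/0 as
  infinite (an exact-duplicate plateau followed by any positive cost is
  a maximal jump).
* Empty matrix → empty assignment; empty cluster or all-missing
  attribute → summary flagged unavailable rather than NaN arithmetic.
* Welch test with zero pooled variance returns non-finite t and is
  flagged unavailable.
* All randomness flows through `numpy.random.Generator` objects seeded
  from explicit integers; restart seeds derive from
  `numpy.random.SeedSequence(master)`.

## Scale choices

Desk-scale defaults (20×20 map, 20,000-row training sample, 30 epochs,
100,000 synthetic records, 3 restarts) run the full benchmark in under
a minute on one CPU. They are chosen as the smallest configuration at
which the planted-structure recovery is stable; all of them grow
gracefully — the map to ~1,000 nodes and the sample to 200,000 rows via
the same `TrainingSchedule`/`default_grid` parameters.

## Known limitations

* The demo category map is illustrative; study-scale analyses must
  supply their own aggregation table, and results depend on it.
* The adjacency constraint makes cluster shapes depend on map quality;
  the restart criterion mitigates but cannot eliminate topology traps.
* `choose_k` is a heuristic; the package takes k as a user decision.
* Profiling treats records as independent; certificate-level reporting
  artifacts (e.g. over-reporting of cardiac arrest) propagate into
  cluster profiles unmodelled.
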