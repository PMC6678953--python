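# somward

SOM-Ward clustering and statistical profiling of multiple-cause-of-death
(MCOD) records.

Death certificates carry far more than the single underlying cause of
death: up to 20 entity-axis ICD-10 codes describe every health condition
present at death. Clustering decedents by these condition patterns
reveals population-scale multimorbidity structure — which diseases
travel together at the end of life, and how the resulting groups differ
in age, sex, education, marital status, place and manner of death. That
picture matters for planning palliative and end-of-life care.

`somward` implements the full analysis pipeline for researchers working
with MCOD-style vital-statistics files (or, since those files are
restricted, with the bundled synthetic stand-in):

1. **ingest** — parse delimited record tables against a YAML column
   schema, aggregate ICD-10 codes into disease categories via an
   ordered longest-prefix rule map, derive the multimorbidity indicator
   (≥ 2 distinct categories), drop condition-free records, and build
   the binary record × category indicator matrix.
2. **som** — train a batch self-organizing map (SOM) on a seeded random
   sample: node codebooks `m_i` are updated as the Gaussian-kernel
   weighted mean of sample rows,
   `m_i ← Σ_j h(d(c_j,i),σ_t)·x_j / Σ_j h(d(c_j,i),σ_t)`, with
   `h(d,σ)=exp(−d²/2σ²)` over lattice distance and σ shrinking linearly
   across epochs. All records are then mapped to best-matching units.
3. **ward** — SOM-Ward clustering: classical minimum-variance (Ward)
   agglomeration of the map nodes, restricted so only lattice-adjacent
   clusters may merge. The merge cost is the increase in within-cluster
   sum of squares, `w_a·w_b/(w_a+w_b)·‖μ_a−μ_b‖²`, with node weights
   equal to mapped record counts. Clusters are therefore connected
   regions of the map, and every record inherits its node's label.
4. **profiling** — per-cluster attribute summaries (count/percent for
   categorical attributes over the non-missing denominator, mean/SD for
   continuous ones, condition prevalences over the full cluster),
   two-sided Welch t-tests of each cluster against the rest of the
   population at an a-priori p < 0.01, and top-5 condition /
   underlying-cause rankings.
5. **synthetic** — a latent-class population generator with 16 planted
   clusters over a ~35-category demo vocabulary, calibrated to the
   gross margins of the real US 2006–2016 mortality data (≈ 3 conditions
   per record, ≈ 78% multimorbidity, mean age at death ≈ 73).

A statsmodels-style facade ties the stages together: build a
`SomWardModel` from coded records, call `fit()`, inspect the
`SomWardResults`.

## Worked example

```python
from somward import SomWardModel, ingest, som, synthetic

cmap = synthetic.demo_category_map()
spec = synthetic.default_benchmark_spec(n_records=20_000, seed=7)
records, latent = synthetic.generate_population(spec)
coded = [ingest.code_record(r, cmap) for r in records]
usable, omitted = ingest.filter_usable(coded)

model = SomWardModel.from_records(
    usable, cmap.category_vocabulary, k=16,
    grid=som.SomGrid(16, 16),
    schedule=som.TrainingSchedule(n_epochs=30, sigma_start=8, sample_size=20_000),
)
res = model.fit(seed=7)
print(res.summary())
```

prints

```
SOM-Ward clustering results
===========================
Records:              20,000
Disease categories:   36
Map grid:             16 x 16 (256 nodes)
Quantization error:   0.6652 (training: 1.4491 -> 0.6652)
Clusters (k):         16

cluster    records   share  top conditions
      0      2,345   11.7%  other_cancer (99.5%), breast_cancer (29.4%), diabetes_mellitus (8.1%)
      1      2,296   11.5%  atherosclerotic_heart_disease (99.7%), myocardial_infarction (30.0%), respiratory_failure (7.2%)
      2      2,049   10.2%  heart_failure (99.5%), hypertensive_heart_disease (75.8%), hypertension (30.7%)
      ...
     15        561    2.8%  non_hodgkin_lymphoma (98.9%), prostate_cancer (84.3%), urinary_tract_infection (35.3%)
```

Each row is one connected region of the map: its record count, its
share of the population, and the conditions most prevalent among its
decedents. The quantization error (mean record-to-codebook distance)
dropped from 1.45 at initialization to 0.67, and the recovered clusters
line up with the generator's planted structure. Cluster profiles with
significance tests come from `res.profiles`, per-node attribute maps
from `res.component_plane("age_years")`, and a population
characteristics table from
`somward.profiling.format_population_table(res.profiles[1])`.

The same pipeline runs from the shell:

```bash
somward run --config config.yaml --seed 1
somward simulate --n 100000 --seed 1 --out records.csv
somward code --input records.csv --out coded.csv
```

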