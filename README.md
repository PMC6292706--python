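# rcdkit

Tools for testing the causes of **reproductive character displacement**
(RCD) in a pair of sister species — the situation where mating traits or
assortative mating are more divergent where the two species co-occur
(sympatry) than where each occurs alone (allopatry). Three processes can
produce that pattern and they leave different footprints: **reinforcement**
(selection against hybrids, requiring gene flow after contact),
**reproductive interference** (costly heterospecific matings between fully
isolated species, no gene flow), and **differential fusion** (only
already-divergent population pairs persist in sympatry). `rcdkit`
implements the full inferential chain needed to tell them apart in a
system like the mangrove snails *Littoraria cingulata* and *L. filosa*:

- **`rcdkit.mating`** — assortative mating from no-choice trials. The joint
  isolation index is built from PSI pair coefficients,
  `psi_ij = O_ij / E_ij` with `E_ij = row_i · col_j / T` over the 2×2 table
  of mated pairs, and

  `I_PSI = (psi_CC + psi_FF − psi_CF − psi_FC) / (psi_CC + psi_FF + psi_CF + psi_FC)`,

  0 under random mating, 1 under complete assortment, insensitive to
  sexual selection. Inference is by bootstrap over the mated pairs
  (`t = I_PSI / SE`). GLM likelihood-ratio tests for the
  male species × female species × location interaction cover displacement
  in mounting probability and mount duration, and a logistic model links
  insemination (sperm in the bursa copulatrix) to mount duration.
- **`rcdkit.morphometrics`** — genital-trait analysis: pooled-regression
  size adjustment of 9–10 linear penis measurements to the mean overall
  length, trajectory analysis of the between-species vector in sympatry vs
  allopatry (path-distance and direction tests with residual-randomization
  permutation nulls), covariance PCA, and per-trait interaction tests with
  Bonferroni correction.
- **`rcdkit.popgen`** — genotype QC (first SNP per sequencing tag, exact
  Hardy–Weinberg filtering per region, call-rate filtering), genotype PCA,
  Nei pairwise F<sub>ST</sub>, and F1-hybrid diagnosis from
  species-diagnostic SNPs.
- **`rcdkit.demography` / `rcdkit.abc`** — coalescent simulation (msprime)
  of four secondary-contact scenarios that differ only in interspecific
  gene flow after contact — none (NM), constant (CM), recent (RM), ancient
  (AM) — summarized over short non-recombining sequence tags, and
  approximate Bayesian computation: model choice via a discriminant
  classifier on sympatric-vs-allopatric contrast statistics (rejection and
  multinomial-logistic neighborhood estimators as options), parameter
  posteriors by rejection with local-linear regression adjustment,
  leave-one-out cross-validation and goodness-of-fit projection.
- **`rcdkit.synth`** — generators for every input (trial records, feature
  tables, genotypes from paired simulated haploids), so the whole pipeline
  runs end-to-end without external data.

## Worked example

```python
from rcdkit.datasets import mating_trial_table
from rcdkit.mating import IsolationIndexModel

table = mating_trial_table("sympatric")   # published trial outcomes
res = IsolationIndexModel(table).fit(n_boot=10_000, seed=7)
print(res.summary())
```

```
Joint isolation index (sympatric)
--------------------------------------------
I_PSI           0.5537
n matings      119
PSI CxC         1.3511
PSI CxF         0.2218
PSI FxC         0.6661
PSI FxF         1.7399
SE (bootstrap)  0.0765   (n_boot=10000, seed=7)
t = I/SE        7.238
P (bootstrap)   9.999e-05
P (normal)     4.567e-13
```

Sympatric mating is strongly assortative (conspecific pairings mate far
more often than expected, `PSI CxF = 0.22` means heterospecific C♀×F♂
pairs mate at 22% of the random-mating expectation); the same analysis on
the allopatric table gives I_PSI ≈ 0.13 with t ≈ 1.8 — assortment only in
sympatry, the RCD signature.

An end-to-end synthetic run (generation → all four analyses → JSON
report):

```bash
rcdkit run --config run.yaml     # see rcdkit.pipeline.RunConfig for keys
```

or per-stage CLIs, e.g.

```bash
rcdkit mating ipsi --trials trials.csv --location sympatric --n-boot 10000 --seed 42
rcdkit morph trajectory --features penes.csv --n-perm 999 --seed 7
rcdkit demog simulate --model NM --n-tags 200 --seed 1 --out tags.fasta
```

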