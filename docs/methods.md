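# Methods

## Assortative mating: the joint isolation index

A no-choice mating trial pairs one male and one female (always from
different sites, so site assortment cannot masquerade as species
assortment) and records whether at least one mounting occurred within the
observation window. Trials are tabulated per location class into a 2×2
table of mated pairs by (female species × male species); trials without
usable outcome data are dropped and counted.

PSI pair coefficients divide the observed matings in each cell by the
count expected under random mating. The expected counts are built from the
products of the *mating-event marginals* (`E_ij = row_i · col_j / T` with
`T` the number of matings), not from the numbers of trials conducted: PSI
conditions on who mated and asks only whether the pairings were assorted,
which is what makes `I_PSI` insensitive to sexual selection (one species
simply mating more moves both marginals and cancels). `I_PSI` is the
normalized contrast of homospecific against heterospecific coefficients
and lies in [−1, 1].

**Bootstrap.** The `T` mated pairs are resampled with replacement from the
multinomial over the four pair types and `I_PSI` recomputed per replicate;
`SE` is the replicate standard deviation, `t = I_PSI / SE`. By default the
expected frequencies stay fixed at the observed table's values — the
premating reference is treated as data, the convention of the
mating-frequency literature this index comes from — while
`recompute_expected=True` rebuilds them per replicate (replicates whose
marginals empty are redrawn, at most 100 attempts, the count reported).
Two two-tailed p-values are reported because the reference distribution of
`t` is not canonical: a percentile bootstrap p (replicates centered at
zero) and a normal approximation of `t` against N(0, 1).

**GLM tests.** Displacement is the male species × female species ×
location interaction. For mounting, a binomial GLM with researcher and
time-block covariates; for duration, a Normal-error model of the natural
log of the per-trial *mean* mount duration (multiple mounts per trial are
collapsed to their mean) with male size, female size, their difference and
female maturity as covariates. All tests are likelihood-ratio (df = 1)
with treatment coding; a df-0 comparison (empty or collinear cells) is an
error rather than a silent NaN, and separation in a logistic fit sets a
flag on the result. The sperm model is a plain logistic regression of
sperm presence in the bursa on log mean duration; its slope is the
per-log-minute effect on the logit scale.

## Morphometrics

Features are linear measurements in mm, labelled A–K with A the overall
length; one feature that cannot be measured in every specimen is dropped
via a parameter (never hard-coded). Size adjustment uses a single pooled
regression slope per feature (all individuals together):
`y_adj = y − b (A − mean A)`. A pooled slope cannot leak group mean
differences into the size correction; the cost is a slightly biased slope
if allometry truly differs between groups. When length barely varies but
differs between species, the pooled slope absorbs the species difference —
an inherent property of size correction, worth knowing when simulating.

**Trajectory analysis.** The species-difference vectors
`v_loc = mean(filosa, loc) − mean(cingulata, loc)` are compared between
locations by magnitude (`|d_symp − d_allo|`), direction (angle between the
vectors, degrees), and a two-factor multivariate interaction F built from
the trace of the cell-mean sums of squares. The permutation null holds the
additive model (species + location main effects fitted by least squares),
permutes its residuals across all individuals, and adds them back to the
fitted values — so permuted data keep the common species offset but carry
no location-specific change in it, which is the null all three statistics
test. p = (1 + #{perm ≥ obs}) / (1 + B), B = 999 by default (199 in the
calibration studies below); the observed statistic counts in both
numerator and denominator, so p ∈ (0, 1]. All three statistics are
invariant to rotation and translation of feature space (tested).

PCA is on the covariance matrix of the adjusted features (all in mm —
correlation-matrix PCA would discard the size structure that remains
biologically meaningful after adjustment), with PC1 signed so the filosa
mean score is positive. Per-trait tests are univariate two-way interaction
F tests with Bonferroni correction over the tested features; constant
features are skipped with a warning.

## Population genetics

The genotype matrix holds biallelic SNPs as alternate-allele dosage with
per-locus tag metadata. Filtering: (1) first SNP per tag by position,
avoiding intra-tag linkage; (2) exact Hardy–Weinberg test per
region × species group, dropping a locus if P < 0.01 in *any* group —
by default the mid-P variant (the observed outcome contributes half its
probability), which is better calibrated at n ≈ 15 per group; plain exact
P by flag; groups with fewer than 2 genotyped individuals are skipped for
that locus and counted; (3) call rate > 0.80 over all individuals.

Nei pairwise F<sub>ST</sub> partitions expected heterozygosity,
`(H_T − H_S)/H_T` with unweighted two-group means, combined over loci as a
ratio of sums with negative per-locus components retained; a negative
final entry is clamped to 0 and the pair flagged. Genotype PCA mean-imputes
missing calls per locus and centers per locus. Hybrid diagnosis: loci with
an allele-frequency difference ≥ 0.95 between reference panels are
diagnostic; an individual heterozygous at every genotyped diagnostic locus
(minimum 5) is an F1, homozygous throughout for one species' alleles is
parental, a het/parental mixture is backcross-like, anything else
ambiguous.

## Demographic models and coalescent simulation

Four sampled populations: allopatric and sympatric regions of each
species. Backwards in time, regions merge at `t_reg_c` / `t_reg_f`
(generations), species at `t_sp`; current sizes `n_now`, ancestral
branches `n_anc` (haploid effective sizes — samples are single alleles per
individual). `m_intra` migrants/generation link the two regions of each
species until they merge. The models differ only in migration between the
two sympatric populations after secondary contact at `t_sc` (default 10⁴
generations, configurable): never (NM), throughout [0, t_sc] (CM), only
recently [0, t_rm] (RM), or only anciently [t_am, t_sc] (AM). Migrant
counts are converted to msprime rates as `m / n_now`.

Each locus is an 82-bp non-recombining tag. Genealogies come from msprime
(`ploidy=1`, independent replicates per tag); infinite-sites mutations are
placed directly on each genealogy — Poisson in rate × length × total
branch length, branch chosen proportional to its length, position uniform
and continuous — which is exact for this mutation model and avoids
per-tag mutation-engine overhead. Mutation-rate heterogeneity across tags
is Gamma with shape 2 and mean μ (constant by option). Monomorphic tags
are excluded and counted, matching how observed tag data are prepared.

**Summary statistics** (116 entries, fixed order): per population, mean
and variance across tags of segregating sites S, nucleotide diversity π,
and Tajima's D (over tags where defined), plus the deciles of π; per
population pair, mean and variance of Hudson's F_ST (within-tag ratio of
sums), d_xy, and counts of shared and private polymorphisms, plus the
deciles of F_ST and d_xy. The decile statistics matter for model choice:
recent gene flow leaves a *tail* of unusually low-divergence tags that
means and variances wash out. Variances use the population (ddof = 0)
convention so single-tag datasets stay finite.

## ABC

Reference tables draw parameters from uniform priors — `t_sp` uniform on
[10⁵, 2×10⁶] generations, region splits uniform on [10⁴, t_sp]
conditional on the drawn `t_sp`, sizes and migration rates log-uniform
(`n_now` [10⁴, 10⁷], `n_anc` [10³, 10⁶], `m` [10⁻⁴, 10]), RM/AM window
endpoints uniform within (0, t_sc); generation time 1 year for any
conversion to years. All priors are configuration, not constants.

Statistics are standardized by a robust scale: the median absolute
deviation over the pooled simulations, floored at a fifth of the standard
deviation (heavily discrete statistics such as deciles and counts can
have a near-zero MAD while their spread is real, and a near-zero scale
would blow up the standardized values); columns with no variation are
ignored with a warning.

**Model choice.** The four models differ *only* in sympatric
interspecific migration, so before any inference the statistics are
reduced to paired sympatric-vs-allopatric contrasts
(`contrast_features`): between-species divergence at the allopatric pair
minus the sympatric pair (the cross pairs serve as additional controls),
and within-species sympatric-minus-allopatric diversity. These
differences cancel the shared nuisance parameters — split times, sizes,
mutation rate — that otherwise dominate any distance or classifier and
flatten the posterior toward uniform. Under no migration every contrast
is a within-dataset exchangeable difference centered at zero; migration
shifts and overdisperses specific contrasts.

The default estimator is classification-based model choice: a regularized
quadratic discriminant classifier trained on the MAD-standardized
contrasts of the reference table, evaluated at the observed vector. Its
class probabilities rank the models near-optimally (it effectively asks
"is there a detectable migration signal, and with what timing?"), but as
plug-in Gaussian probabilities they are sharper than a calibrated
posterior — on genuinely ambiguous data they overstate certainty.
Kernel-weighted neighborhood estimates are available as `rejection` and
`mnlogistic`: statistics standardized by MAD, projected onto the
linear-discriminant axes separating the models, nearest `tolerance`
fraction retained with Epanechnikov weights, posterior from the weighted
model shares or a weighted multinomial logistic regression. These are
better calibrated but noisier rankers at desk scale: because most of the
migration models' prior mass is observationally equivalent to no
migration (log-uniform migrant numbers down to 10⁻⁴), their posteriors
for data without a migration signal hover near 0.35/0.22/0.22/0.22 and
estimation noise can flip the argmax. Posteriors are renormalized to sum
to 1; a model with no retained simulations gets posterior 0 with a
warning.

**Parameter estimation.** Within the chosen model's simulations:
rejection (default tolerance 0.25) plus local-linear regression
adjustment. Every parameter is first logit-mapped to its position within
its prior support (on the log scale for log-uniform parameters; the
region splits relative to their `t_sp`-dependent bound, the RM/AM
windows relative to `t_sc`), so adjusted draws can never leave the prior
range — without this bounding, occasional extrapolations of the local
regression produce absurd back-transformed values. A full-rank
regression on all the statistics overfits the few hundred retained
draws, so the regression uses at most 20 weighted principal components
of the retained standardized statistics (never more than a tenth of the
retained count). Posterior summaries are weighted quantiles and a
weighted-KDE mode.

Cross-validation classifies held-out reference simulations with
themselves excluded (leave-one-out). Goodness of fit projects the
observed vector into the PCA plane of the pooled simulations and flags it
inside/outside each model's 95% envelope, defined by the quantile of that
model's own squared Mahalanobis distances (a convex elliptical envelope).

## Synthetic data

The trial generator's default per-cell mounting probabilities are the
published trial outcomes themselves (counts/totals per cell), so the
expected sympatric `I_PSI` of generated data is ≈ 0.55; durations are
log-normal with conspecific mounts long everywhere and heterospecific
mounts short in sympatry only; insemination follows a logistic model in
log duration with slope 0.59 per log-minute (the published effect size)
and intercept −2.4 (even odds at ≈ 60 min); researcher and time block
rotate in balanced batches of 20 with three morning and three afternoon
batches per cycle. The morph generator adds a shared allometric slope and
multivariate-normal noise around species × location group means; its
`sympatry_offset_scale` dial creates (or removes) true character
displacement. Diploid genotypes pair consecutive simulated haploids
within a population — random pairing under the coalescent, hence
Hardy–Weinberg within region, which is exactly what the HWE filter
assumes. What the generators do *not* emulate: observer effects
correlated with outcomes, linked SNPs within a tag beyond their shared
genealogy, sequencing error, and spatial structure below the region
level — so passing tests validate the statistical machinery, not the
robustness of the pipeline to those real-data complications.

## Problem sizes and numerical choices in the test suite

Desk-scale settings keep the whole suite to minutes while leaving every
check statistically meaningful: ABC self-consistency uses 2,000
simulations per model, 200 tags, 5 haploids per population, tolerance
0.1, 20 pseudo-observed datasets generated at the prior midpoint (model
recovery is strongly table-size dependent — roughly 40% correct at 500
simulations per model, 85% at 1,000–2,000); parameter recovery reuses the
same table's no-migration half with leave-one-out pseudo-observations;
null calibrations run 500 replicates with 199 permutations and 30
individuals per group (trajectory) or 50 trials per cell (GLM); simulator
analytics use 2,000 tags. Bootstrap and permutation inference always
require an explicit seed; every simulation is reproducible bit-for-bit
given (seed, settings). The pipeline derives independent per-stage seeds
from the global seed via a seed sequence keyed on the stage id, so stages
rerun alone reproduce their in-pipeline results.

## Known limitations

- The fixed-reference bootstrap reproduces the conventional `t` for these
  tables; the fully recomputed variant gives SEs a few percent smaller.
  Neither is "the" SE — the choice is reported with the result.
- The trajectory magnitude test is slightly anticonservative at very
  small groups (rejection ≈ 0.06–0.07 at n = 15/group); calibration is
  comfortable from n ≈ 30.
- RM, CM and AM collapse onto NM as `m_inter → 0`, so model posteriors
  cannot concentrate fully on NM even with perfect data; the self-
  consistency check asks for the correct *ranking*, not a posterior near 1.
- Tag FASTA output floors continuous mutation positions to integer
  coordinates; co-located site pairs (rare) are merged on round-trip.
- The F1/backcross rules assume truly diagnostic loci; with panels of a
  few individuals, apparent fixed differences can be sampling artifacts.
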