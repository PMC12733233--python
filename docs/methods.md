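# Methods

## Data model

Genotypes are biallelic codes relative to a declared minor allele: 1 =
homozygous major, 2 = heterozygous, 3 = homozygous minor; missing values are
kept as NaN and excluded per locus (complete-case per SNP), so per-table
totals may differ between SNPs. Phenotypes carry a binary case/control
`status`, the four binary injury sub-phenotypes (ACLF single-vs-multiple
injury, ACLS strain, ACLRP partial rupture, ACLRC complete rupture) defined
only for cases, and the age (years) and body-mass (kg) covariates. Cohorts
are inner joins of the two tables on case-sensitive sample ids; duplicate
ids are an error, and drop counts per side are reported.

The published case–control count tables carry a column-label inconsistency
(the column headed "Cases" sums to the stated control-group size of 136, the
other to ~158). The package resolves group membership by column sums, not
headers; both interpretations are retained in `study.CASE_CONTROL_COUNTS`
and the 136-sum column is treated as the control group by default. This
default is also what the power analysis uses for "MAF estimated in
controls"; it is supported by the published recessive-model remark at MAF
0.15, which matches the 136-column rs486055 frequency (0.151).

## Single-locus statistics

Inheritance models collapse the three genotypes into contrasts: codominant
(each genotype vs the code-1 reference, one 2-df test), dominant ({2,3} vs
{1}), recessive ({3} vs {1,2}), overdominant ({2} vs {1,3}), log-additive
(allele dose 0/1/2). The minor allele is the risk allele throughout.

Crude odds ratios are cross-product ratios with Woolf (log-OR normal)
intervals. Zero-cell policy: no continuity correction; a zero exposed-case
or unexposed-noncase cell gives OR 0, the opposite diagonal gives an
infinite OR, and the interval is omitted whenever any cell is zero (rendered
"0.00 (0.00)" in reports, matching the published style). Model-level
p-values default to the likelihood-ratio (G) test on the contingency table
(Pearson chi-square available); covariate-adjusted estimates come from
maximum-likelihood logistic fits with a likelihood-ratio test of the
genotype term (2 df for codominant). Perfect separation is flagged on the
estimate rather than raised. Both crude and adjusted estimators are exposed;
the published within-case tables are numerically crude cross-product ratios,
while the published case–control tables are covariate-adjusted and cannot be
reproduced from counts alone — the package therefore validates that pathway
by parameter recovery on synthetic cohorts instead.

FDR control uses Benjamini–Hochberg step-up within two declared families:
the case–control family (3 SNPs x 4 models, m = 12, codominant counted
once) and the within-case family (3 SNPs x 4 outcomes x 4 models, m = 48).

The exact Hardy–Weinberg test enumerates every heterozygote count compatible
with the observed allele counts and sums the conditional probabilities of
tables no more probable than the observed one (two-sided); computation is in
log-space and is exact to floating-point rounding (verified against an
integer-fraction enumeration oracle for all n ≤ 200). A 1-df Pearson
chi-square against p², 2pq, q² expectations is reported alongside because
published HWE p-values rarely state their method. Monomorphic loci return
p = 1.

## EM haplotype analysis

Phase ambiguity is treated as missing data. For each distinct multilocus
genotype the compatible unordered haplotype pairs are enumerated (2^(h-1)
for h heterozygous loci); the E-step weights each pair proportionally to the
product of current frequencies (doubled for heterogeneous pairs), the M-step
re-estimates frequencies from expected counts, and the log-likelihood is
asserted non-decreasing at every iteration. Initialisation is uniform over
compatible haplotypes; optional random restarts (Dirichlet starts, seeded)
guard against the rare multimodal likelihood. Individuals missing any panel
genotype are dropped listwise. Convergence: log-likelihood gain < 1e-8
(default), cap 1000 iterations; non-convergence returns the best iterate
with a warning.

The haplotype–outcome GLM uses additive haplotype-dose coding against the
most frequent haplotype as reference, pooling haplotypes rarer than 0.01
(configurable). Each individual's design row is expanded over compatible
pairs with phase-posterior weights, and the weighted logistic fit and
posterior update are alternated to convergence — this is an EM algorithm
whose stationary point maximises the observed-data mixture likelihood.
Wald variances are taken from the numerical Hessian of that observed-data
log-likelihood at the optimum. This matters: variances from the final
weighted GLM alone ignore the outcome-informed phase feedback and were
measurably anti-conservative in a 250-replicate null calibration (9.2%
rejection at nominal 5%); the observed-information correction restores 5.9%,
and per-haplotype rates of 3–6% over 400 further replicates. On phase-free
data the procedure reduces exactly to ordinary logistic regression (checked
to 1e-6 against the single-locus log-additive fit).

## Logic regression

Each SNP contributes two binary dummies: `SNP_1` (at least one minor
allele) and `SNP_2` (homozygous minor); the encoding is a bijection on the
27 joint genotypes of the 3-SNP panel. A logic tree — a binary AND/OR tree
over dummies and complements, at most 10 leaves — classifies "predict case
where true" and is fitted by simulated annealing over the moves grow-leaf,
prune, change-operator, change-variable and toggle-complement. Scoring
collapses rows to distinct binary patterns first (≤ 64 here), so each
proposal costs a small vector evaluation. The start temperature is
calibrated so a typical uphill move is accepted ~90% of the time; cooling is
geometric (default ×0.98 per block of 30 moves over four orders of
magnitude). Fits are bit-for-bit reproducible under a fixed seed.

Fitted trees are decomposed into **prime implicants** via Quine–McCluskey
over the tree's support variables; each implicant is an "interaction". Over
`n_bootstrap` bagged fits (default 100), an interaction's *proportion* is
the fraction of models containing it and its *OOB importance* is the summed
drop in out-of-bag accuracy when it is removed from models containing it,
divided by the total model count — so an interaction must appear often
*and* matter when present to score high. (Normalising instead by the count
of containing models was evaluated and clearly weakened planted-signal
separation, 5/8 vs 8/8 detection in a seeded benchmark.)

Inference repeats the whole bagging run `n_iter` times on the real labels
and `n_iter` times on freshly permuted labels with identical settings.
Interactions with mean real proportion > 0.15 receive bootstrap percentile
CIs (2000 resamples) of their per-iteration importance in both arms. An
interaction is flagged when its real CI lies entirely above **both** (a) the
range of its own per-permutation null importances and (b) the median over
permutations of the maximum importance any interaction reaches in that
permutation (the "typical best chance interaction" level).

This construction was chosen over the textbook alternative — comparing the
real CI-of-mean against a null CI-of-mean — after a seeded benchmark of 20
label-permuted (double-null) and 20 planted-conjunction datasets (OR 3,
296 samples, 50-iteration reduced protocol).  Every fixed label vector,
including a permuted one, carries chance associations that persist between
in-bag and out-of-bag samples; a null CI-of-mean only reflects protocol RNG
noise, so the textbook rule flags chance-level structure even on
label-permuted input.  Component (a) alone still false-flags interactions
that star in the fixed dataset but rarely recur across permutations
(their own null sample is spuriously narrow); component (b) repairs
exactly that failure mode.  Measured operating characteristics on the
benchmark: 2/20 double-null datasets with any flag, 16/20 planted
conjunctions detected.  The residual misses are datasets whose realized
planted association is chance-level — doubling the annealing schedule did
not recover them, so this is a power limit of the design, not of the
search.

Protocol sizes: the package default follows the full protocol (100
bootstraps, 200 iterations), which is an overnight computation. The test
suite and the acceptance script run a reduced protocol chosen to preserve
the protocol's operating characteristics at interactive runtimes: 15
bootstraps, a shortened annealing schedule (cooling ×0.9, 6 moves per
temperature), and 50 iterations per arm.
The seeded benchmarks above were run at these reduced sizes.

## Power and minimal detectable odds ratio

Controls carry HWE genotype probabilities at the control minor-allele
frequency; a logistic disease model with odds ratio `OR` per unit of the
genetic coding tilts the case genotype distribution by `OR^coding`
(retrospective sampling with fixed group sizes). The test is the 1-df score
test of the genetic term. For the binary codings (dominant, recessive) the
score statistic is the Pearson chi-square of the collapsed 2×2 table and
power is computed **exactly** by enumerating the two binomial margins; for
the additive coding a normal approximation with the exact retrospective
mean and variance of the score statistic is used. Against Monte-Carlo
rejection rates (2000 simulations per cell) the maximum discrepancy on the
study's model × MAF grid at OR 2 is under one percentage point. At OR 1 the
additive formula returns exactly alpha; the exact binary computation sits at
or slightly below alpha, as a discrete test must.

The MDOR search scans odds ratios 1.01–10 in 0.01 steps and returns the
first grid point whose power reaches the target (0.80/0.90); an unreachable
target is reported as an open bound (">10"-style), which is how the
recessive model at low MAF behaves.

## Synthetic cohorts

The generator's defaults are the study conditions: 160 cases / 136
controls; control-group frequencies of the declared minor alleles from the
136-sum columns (I 0.540, T 0.151, G 0.110); age 27±4 (controls) vs 36±7
(cases) years and body mass 73±16 vs 78±10 kg, drawn Normal per group;
sub-phenotype prevalences from the within-case table margins (ACLF multiple
0.365, ACLS 0.805, ACLRP 0.25, ACLRC 0.119), assigned as independent
Bernoulli draws among cases (the published strata overlap, so overlapping
subtypes are allowed). SNPs are independent by default — no linkage
information is published for the three loci — with an optional joint
haplotype distribution for LD. Genetic effects (per-model genotype ORs, or
a Boolean expression over joint genotypes with a target OR) are planted by
tilting the case-group genotype distribution, which is exactly the
case-control sampling a logistic disease model induces; covariate effects on
the outcome default to zero, so the groups differ demographically without
confounding the genetics. Missingness is uniform at a configurable rate.
A fixed seed reproduces cohorts byte-for-byte.

What the generator does **not** emulate: population structure or
relatedness, genotyping error beyond uniform missingness, LD estimated from
real data, covariate–genotype correlation, and any true effect sizes of the
study — recovery tests demonstrate that the estimators are consistent and
calibrated under the model they assume, not that the study's specific
findings replicate.

## Known limitations

* The case–control odds-ratio tables of the study are covariate-adjusted
  and cannot be reproduced without individual-level data; the package's
  adjusted-logistic pathway is validated by synthetic parameter recovery
  only.
* The haplotype GLM's observed-information variance is numerical (central
  differences); with many haplotype columns and near-separation it can be
  unstable, in which case the naive weighted-GLM variance is the fallback.
* Logic-regression results at reduced protocol sizes are noisier than the
  full 200×100 protocol; single borderline interactions near the proportion
  threshold may flicker between runs with different seeds.
* The exact power enumeration is O(n_cases × n_controls) per grid point and
  is intended for cohort-scale designs, not biobank-scale ones.
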