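# Methods

This note documents the models implemented in `maizegs`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one convention is
defensible.

## The breeding program being modelled

The package models a two-stage testcross program for tropical maize DH
lines. In stage I a cohort of bi-parental DH families is genotyped with
low-cost dominant (presence/absence) sequence-tag markers; roughly half the
lines are crossed to a tester and evaluated in replicated alpha-lattice
trials at several well-watered (WW) locations and one managed-drought (WS)
location, while the other half is only genotyped. Phenotyped lines are
advanced on above-average BLUEs (phenotypic selection, PS); unphenotyped
lines are advanced on above-average GEBVs predicted from the phenotyped half
(genomic selection, GS). In stage II both cohorts are crossed to common
testers and compared head-to-head against commercial checks. The economic
argument is that GS buys the same selection outcome for roughly two-thirds
of the phenotyping budget.

## Synthetic data generator (`maizegs.simdata`)

**Genome and families.** Each DH line is a single F1 gamete doubled to
homozygosity. Crossovers follow the Haldane model — a Poisson process at one
event per Morgan, no interference — on equally spaced marker maps (default
10 chromosomes of 150 cM; the stage-I default map carries 4657 markers).
Interference would not change any downstream statistic tested here, which is
why the simplest standard model is used. Families segregate 1:1, and marker
codes are dominant 0/1 tags (presence of the parent-A allele); an `additive`
option emits 0/2 dosages. The default family sizes (34…240, twelve families,
1492 lines) reproduce the census of the emulated stage-I cohort.

**Genetic values.** Additive values come from 100 QTL placed uniformly at
random among marker positions, with independent normal effects per
management level, rescaled so the line-set variance of g equals the
configured sigma2_G *exactly* (population variance, divisor n). Rescaling
makes recovery targets exact rather than asymptotic. WW and WS genetic
values use independent effect draws: the two regimes are treated as separate
traits, which is the weakest (most conservative) assumption for tests that
span both. Line-by-location deviations gE are drawn iid
N(0, sigma2_GxE) per WW environment; the WS regime is single-environment by
design, so its truth has no interaction term.

**Trials.** Plot value = management mean + location effect + rep-within-
location effect + incomplete-block effect + g (+ gE in WW) + residual, all
Gaussian at configured variances. Defaults follow the emulated program's
stage-I grain-yield components: WW (sigma2_G, sigma2_GxE, sigma2_e) =
(0.19, 0.18, 1.41) t^2/ha^2 around a 6.03 t/ha mean; WS (0.17, –, 0.33)
around 3.25 t/ha. Block and rep variances (0.05, 0.02) and the location
variance (0.42) are package choices of realistic magnitude; the location
variance matches the printed environmental variance for WW grain yield.
Commercial checks are fixed-value entries replicated in every trial and
excluded from the marker matrix, mirroring programs where checks have
phenotypes but no genotype data. Everything derives from one integer seed
(`numpy.random.default_rng`); identical configs are byte-identical.

**What the generator does not emulate:** linkage disequilibrium decay
calibrated to real maize, non-Gaussian residuals, spatial field trend,
missing-plot mechanisms, genotype-by-management correlation, and epistasis
or dominance. Passing recovery tests therefore demonstrate correctness of
the estimators under their own assumptions, not robustness to field
artefacts.

## Mixed models (`maizegs.pheno`, engine in `maizegs._reml`)

Three variants over plot records:

* multi-location: `Y = mu + L + R(L) + B[R(L)] + G + GxL + e`
* single-location (WS): `Y = mu + R + B(R) + G + e`
* across-trials: multi-location plus a fixed trial effect, entries linked
  through shared checks (a union-find connectivity check warns when trial
  groups share no entries).

Location, replicate and trial are fixed; blocks are always random. BLUEs
come from a genotype-fixed fit (with GxL random); variance components, BLUPs
and the h2/LSD/CV summaries come from a second genotype-random fit. Two fits
are needed because entry means and sigma2_G cannot come from one model; this
follows the convention of the standard trial-analysis software in this
field. BLUEs are adjusted entry means — the fitted value averaged over the
levels of every other fixed factor — with standard errors from the GLS
covariance; entries seen in a single replicate remain estimable with larger
SEs. Missing plots are simply dropped: the mixed model handles
unbalancedness natively and no imputation is attempted.

**REML algorithm.** Average-information (AI) REML with EM-REML fallback.
All functionals of `V = sigma2_e I + sum_i sigma2_i Z_i Z_i'` are evaluated
through the Woodbury identity on the stacked sparse incidence matrix, so the
dense work is O(q^3) in the number of random levels rather than O(n^3) in
plots. The first step is EM; afterwards each AI step is accepted only if the
restricted likelihood does not decrease, with step-halving and clamping of
negative proposals to a floor of 1e-8 x var(y); if no damped AI step
improves, the EM update (always uphill, always in the parameter space) is
taken. Convergence: largest absolute component change below 1e-9 x var(y),
cap 200 iterations. A component parked at the floor is reported as 0.
On balanced designs this reproduces the closed-form ANOVA
(expected-mean-squares) estimators to machine precision, and on a frozen
unbalanced fixture it matches an independent reference REML implementation
(lme4) to ~1e-4 relative.

**Summaries.** Entry-mean heritability
`h2 = sigma2_G / (sigma2_G + sigma2_GxL/l + sigma2_e/(l r))` for l locations
and r replicates (the GxL term is dropped for single-location fits);
`LSD = t_{1-alpha/2, df_e} sqrt(2 sigma2_e/(l r))` with df_e = n - p;
`CV% = 100 sqrt(sigma2_e) / grand mean`. Note that the standard formula is
asserted, not any particular published h2 value: trial reports do not always
state the effective l and r behind their printed heritabilities.

## Genomic model (`maizegs.genomic`)

**GRM.** `G = Xs Xs'/p` with markers mean-imputed (per marker), centered and
scaled by the divisor-n standard deviation. The divisor-n choice pins
`mean(diag(G)) = 1` exactly, which the tests exploit as a hard invariant;
after standardization the 0/1 vs 0/1/2 coding question is moot. Monomorphic
markers are dropped; an all-missing line is an error naming the line.

**Model.** `y_ij = mu + E_i + g_j (+ gE_ij) + e_ij` on line-by-environment
means, `g ~ N(0, G sigma2_g)`, interaction
`gE ~ N(0, (Z_g G Z_g') ∘ (Z_E Z_E') sigma2_gE)` (Hadamard product of the
genomic and environment-incidence kernels — block-diagonal across disjoint
environments), residual iid. Flat priors on mu and E; scaled-inverse-
chi-square priors on all variance components, df 5, scales set so each
random term's prior mode carries an equal share of half the phenotypic
variance (the convention of the Bayesian regression software family this
model descends from). The single-environment `G+e` variant serves the WS
site.

**Sampler.** Gibbs, run in the eigenbasis of G restricted to phenotyped
lines. When every phenotyped line is observed in every environment the
conditional posterior of the eigen-coordinates is diagonal, making one
iteration O(n k); unbalanced data fall back to a dense joint update limited
to 500 phenotyped lines. Chain defaults 15,000 iterations / 5,000 burn-in /
thin 5 with a mandatory seed; posterior means are Rao-Blackwellized
(averages of conditional means), which is why short chains already
reproduce the dense mixed-model-equations solution to three decimals in the
oracle tests. Identical seeds give bit-identical fits. Eigenvalues below
-1e-8 raise (non-PSD input); the tiny negative eigenvalues produced by
duplicate DH lines are clipped to zero, which plays the role of the usual
diagonal jitter.

**Prediction.** Because the likelihood touches only phenotyped lines,
`E[g_miss | y] = G_mo G_oo^+ E[g_obs | y]`: GEBVs for any line in G come
from one fit, a line unrelated to all training lines is predicted at the
prior mean 0, and an exact duplicate of a training line inherits its fitted
value. Per-environment predictions add E_i and, under the interaction
model, the line's gE deviation.

## Cross-validation (`maizegs.crossval`)

Random k-fold partitioning of the *line set* (default k = 5, 100 repeats):
a held-out line is unobserved in every environment, matching the prediction
problem the program actually faces. Folds are drawn uniformly without
stratification by family. Within a repeat the k test-fold prediction
vectors are concatenated before correlating, one Pearson r per environment,
pairwise-complete; the accuracy table reports mean ± sd across repeats.
Each fold's chain seed derives from the fold's line content, so accuracy is
exactly invariant to fold visiting order. Tester scenarios: within-tester
CV per tester subset (testers smaller than k are skipped with a warning);
across-tester CV pools all lines after centering values per tester and
environment, so tester-level mean differences cannot masquerade as genomic
signal.

## Selection and comparison (`maizegs.selection`)

"Above average" is strict (>): ties at exactly the cohort mean — measure
zero for continuous criteria — are not advanced, and an all-equal cohort
selects nothing (with a warning). Top-fraction counts and percent cells use
round-half-up; that single rule reproduces every count the emulated program
prints that is reproducible at all (e.g. 15% of 526 -> 79, of 516 -> 77).
`round_half_up` adds a 1e-9 epsilon so exact .5 ratios computed in binary
floating point (such as 11.7/7.2) land on the intended side. Stage-II
statistics operate on hybrid (line x tester) values, not line values, and
checks never enter cohort statistics. Advancement-rate shares are
round-half-up percentages of each cohort within the pooled top fraction, so
they sum to 100 ± 1. Missing line-x-tester combinations (failed crosses)
are tolerated throughout.

## Cost model (`maizegs.costs`)

Activity cost = cost/entry x entries x reps/site x rows/site x sites, exact
integer arithmetic for integer inputs; strategy totals are sums; the GS:PS
ratio is rounded to two decimals. The "rows/site" column is treated as an
opaque design multiplier. The bundled stage-I ledger prices testcross
formation at US$10/entry and a two-row yield-trial plot at US$5/entry/rep
across 4 sites, genotyping at US$10/entry, giving PS = 134,280, GS = 91,870,
ratio 0.68.

## Pipeline and problem sizes

The `pipeline` command chains both stages from one JSON config: simulate ->
per-environment BLUEs of the phenotyped fraction -> GRM -> genomic fits per
management (WW uses the interaction model when two or more WW locations
exist; WS uses `G+e`) -> holdout GEBVs -> optional CV -> above-average
advancement (optionally capped at a stage-II capacity per cohort) ->
simulated stage-II trials -> hybrid BLUEs -> comparison table, advancement
shares, cost report. One seed drives every stochastic step; reruns are
byte-identical.

Default problem sizes in the test suite are chosen to exercise each claim at
meaningful power: oracle agreements on toys (n <= 60), parameter recovery
on 40 trials of 400 entries (Monte-Carlo SE of the recovered means is then
a third of the 10% band), the CV-vs-ridge comparison at 500 lines x 1000
markers, and one full-scale run (1492 lines, 4657 markers, 855 phenotyped,
5-fold x 10-repeat CV, 1042-hybrid stage II) that uses 1,500-iteration
chains — Rao-Blackwellization makes longer chains unnecessary for posterior
means at these sizes, and the run completes comfortably on one CPU.

## Known limitations

* The REML engine's dense q^3 step makes fits with tens of thousands of
  random levels impractical; within-program trial sizes are fine.
* The genomic sampler's fast path requires line-balanced records across
  environments (the pipeline's per-environment BLUEs satisfy this by
  construction); heavily unbalanced inputs beyond 500 lines are rejected
  rather than silently slow.
* The trial mixed models carry no explicit tester term. In stage I each
  line meets a single tester, so a tester effect is inseparable from the
  trial structure; in stage II the analysis unit is the hybrid (line x
  tester), so tester variation lives between entries and tester-level
  differences are handled where they matter for prediction — by centering
  in the across-tester cross-validation scenario. A dedicated tester +
  line-x-tester decomposition would only be identified with multiple
  testers per line in one trial series, a design the pipeline does not
  produce.
* Single-trait analysis only; the multi-trait selection indices a real
  program would also consult are out of scope, as are spatial adjustment,
  outlier rules, pedigree (or blended) relationship matrices, and
  per-marker shrinkage models (Bayes A/B/Cpi, LASSO).
* Leave-one-family-out and forward (year-to-year) validation are natural
  extensions not implemented here.
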