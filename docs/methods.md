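# Methods

## Setting

`mrpipe` implements two-sample Mendelian randomization (MR) on GWAS summary
statistics.  An exposure GWAS supplies per-variant effects `bx_j` with
standard errors `sx_j`; an outcome GWAS, measured in a non-overlapping
sample, supplies `by_j` (`sy_j`).  Under the instrumental-variable
assumptions (relevance, independence from confounders, exclusion
restriction), each variant's Wald ratio `theta_j = by_j / bx_j` estimates the
causal effect of the exposure on the outcome, and the package's estimators
combine the J ratios in ways that are differently robust to violations of
the exclusion restriction (horizontal pleiotropy).  Binary outcomes are
handled on the log odds-ratio scale throughout; every estimate is also
reported as OR = exp(beta) with a normal-theory 95% interval.

## Instrument selection

Selection follows the standard order, each step appending counts to an audit
log:

1. **p-value threshold** — strict `p < threshold`; genome-wide 5e-8 primary
   with a configurable locus-wide fallback (5e-6 or 1e-5) that engages when
   fewer than `min_instruments` (default 3, MR-Egger's minimum) survive.
2. **LD clumping** — greedy by ascending p (ties broken lexicographically by
   SNP id): a candidate is kept unless an already-kept SNP within
   `window_kb` (default 10,000 kb, |position difference| on the same
   chromosome) has `r^2 >= r2_max` (default 0.001) with it.  Without an LD
   matrix the distance criterion alone excludes.
3. **confounder exclusion** — a user-supplied id list replaces interactive
   phenotype-lookup screening; removals are logged with reasons, and absent
   ids are logged no-ops.
4. **weak-instrument filter** — per-SNP `F = (beta/se)^2` (squared Wald
   statistic) must reach `f_min = 10`.  A group F statistic is also reported
   when allele frequencies are available, via the standardized-trait
   variance-explained approximation `R^2 = sum_j 2 eaf_j (1-eaf_j) beta_j^2`
   and `F = ((n-k-1)/k) R^2/(1-R^2)`.  Both variants are computed because
   published analyses cite the group form without printing it; the per-SNP
   form drives the filter.

## Harmonization

Outcome rows are aligned onto the exposure's effect allele: literal match is
kept, swapped alleles flip the outcome beta (and complement its frequency),
and single-base alleles are additionally compared after strand
complementation.  Indel alleles are compared as literal strings only.
Palindromic variants (A/T, C/G) cannot be oriented from allele strings; the
default policy infers orientation by comparing effect-allele frequencies and
drops the variant when either frequency is missing or within 0.08 of 0.5
(`drop` and trust-the-strand `keep` policies are available).  The 0.08
window is a conventional default; the choice is ours, as upstream analyses
typically delegate it to their harmonization library without stating it.
Harmonization is involutive (re-harmonizing aligned data is the identity)
and orientation-invariant (pre-flipping every outcome row is a no-op), and
each dropped variant carries a reason string.

## Estimators

With first-order ratio weights `w_j = bx_j^2 / sy_j^2` (the `sx` term is
ignored, standard in two-sample MR; a second-order option exists and is
recorded when used):

- **IVW**: `beta = sum w_j theta_j / sum w_j`, fixed-effect
  `se = (sum w_j)^{-1/2}`.  The random-effects variant multiplies the
  variance by the overdispersion `max(1, Q/(J-1))`, where Q is Cochran's
  statistic about the pooled estimate; `mode="auto"` (the pipeline default)
  uses random effects exactly when the Q test has p < 0.05 and records the
  choice.  p-values are normal.
- **MR-Egger**: rows are oriented to `bx_j >= 0`, then `by` is regressed on
  `bx` with an intercept, weights `1/sy^2` (via statsmodels WLS).  The slope
  is the causal estimate under InSIDE; the intercept estimates average
  directional pleiotropy.  Both use Student-t inference with J-2 df and
  multiplicative overdispersion floored at 1.
- **Weighted median**: the 50th weighted percentile of the ratios (midpoint
  convention with linear interpolation), consistent when valid instruments
  carry more than half the weight.  SE by parametric bootstrap (resampling
  `bx, by` from their sampling normals; default 1000 replicates, explicit
  seed, both recorded).
- **Weighted mode**: the maximizer of a weighted Gaussian kernel density
  over the ratios; bandwidth is `phi` x Silverman's rule on the weighted
  ratio distribution (phi = 1 by default — the method's originators leave
  the tuning open, so the classical rule is used).  The argmax is located on
  a 1024-point grid and refined by bounded scalar minimization.  Bootstrap
  SE as for the median.

A single instrument falls back to the Wald ratio.  The pipeline records
whether all fitted methods agree in sign ("direction consistent") but does
not auto-label such agreement as positive evidence; that judgement is left
to the analyst.

## Sensitivity suite

- **Cochran's Q** about the IVW estimate, chi-square with J-1 df (J-2 under
  the Egger fit); the same Q drives the fixed/random IVW switch, so the two
  reports can never disagree.
- **Egger intercept test**: two-sided t, J-2 df.
- **MR-PRESSO**: the observed residual sum of squares
  `RSS = sum_j (by_j - theta_hat^(-j) bx_j)^2 / sy_j^2`, with
  `theta_hat^(-j)` the leave-one-out IVW estimate, is compared with its
  Monte-Carlo distribution under simulated pleiotropy-free data
  (`by*_j ~ N(theta_hat^(-j) bx_j, sy_j)`, leave-one-out estimates
  recomputed per simulated dataset).  The global, per-SNP outlier and
  distortion p-values all use the add-one estimator
  `(1 + #exceedances)/(n_sim + 1)`, so they are never zero and have
  resolution `1/(n_sim+1)`.  Outlier p-values are Bonferroni-adjusted across
  J (threshold 0.05 by default — the convention, since published analyses
  rarely state it), which implies a detectability floor of `J/(n_sim+1)`:
  at the conventional 3,000 cycles this supports J up to ~150.  The
  distortion test compares the raw-vs-corrected estimate shift against
  shifts from removing random same-size SNP subsets in the simulated null.
  Flagged outliers are removed once and the estimator battery re-run once;
  the loop deliberately does not iterate.
- **Leave-one-out**: J IVW re-estimates, flagging omissions that change the
  estimate's sign or its significance at 0.05.
- **Funnel data**: per-SNP ratio vs precision `|bx|/sy` with IVW/Egger
  reference lines, emitted as a table (plots are optional and minimal).

## Multivariable MR

`beta_out` is regressed on the J x K matrix of exposure effects without an
intercept, weights `1/sy^2`; each coefficient is a direct effect conditional
on the other exposures.  Overdispersion is floored at 1 and inference is
Student-t with J-K df (consequently the K=1 case reproduces univariable
random-effects IVW's beta and se exactly, while its p-value uses t rather
than the normal reference — both conventions are kept because each is the
field's standard in its context).  An Egger-style intercept (after orienting
rows to the primary exposure) tests directional pleiotropy; a Q with J-K df
measures residual heterogeneity.  Instruments are assembled by the union
rule: each exposure's independently selected instruments are pooled,
re-extracted from all tables, harmonized onto the first exposure's allele
orientation and kept complete-case.  Whether published analyses use the
union or the primary exposure's instruments alone is typically unstated;
union is the documented default, and adjustment is pairwise
(primary + one confounder) by default with a full-joint option.

## Two-step mediation

Three univariable legs (each IVW-auto, Wald ratio if a single instrument):
beta1 (exposure -> mediator), beta2 (mediator -> outcome), beta3 (exposure
-> outcome).  The decomposition is `mediated = beta1 * beta2`,
`direct = beta3 - mediated`, `proportion = mediated / beta3`; additivity on
the log scale is exact by construction, so the OR identity
`OR_direct * OR_mediated = OR_total` holds to machine precision.  The
mediated-effect variance uses the delta method
(`beta2^2 se1^2 + beta1^2 se2^2`); the direct effect adds `se3^2`, treating
the legs as independent — defensible because leg 2 is estimated from a
disjoint instrument set (SNPs selected for the exposure in leg 1 are
excluded from the mediator's instruments in leg 2, a guard against
exposure-driven contamination of the mediator leg).  The proportion is
flagged undefined when `|beta3| < 1e-8` and uninterpretable when mediated
and total effects have opposite signs.  A parametric bootstrap for the
mediated interval is available behind a flag.

One published mediation table row prints a direct effect of 1.193
(1.166–3.140) alongside total 2.055 and mediation 1.074; these are mutually
inconsistent under log-additivity (1.913 would be consistent, suggesting a
digit transposition).  The package reproduces the arithmetic identity, not
that row.

## Synthetic-data generator

The generator emulates the statistical structure of consortium summary
data: per SNP, `eaf ~ U(0.1, 0.9)`; a true exposure effect
`b ~ N(0, 0.35^2)`; analytic standardized-trait standard errors
`se = 1/sqrt(2 n eaf (1-eaf))`; observed effects drawn around the truth with
that noise, independently for exposure and outcome (the two-sample design).
Defaults mirror the consortium designs the pipeline targets: exposure GWAS
n = 18,340 (a gut-microbiome-scale meta-analysis), binary outcome with 287
cases vs 360,143 controls (a biobank dementia endpoint), mediator GWAS
n = 8,293 (a cytokine panel), 30 instruments, true effect theta = 0.2.  The
effect scale 0.35 puts per-SNP F statistics from ~10 into the hundreds,
matching the instrument-strength ranges such studies print.

For binary outcomes the log-OR sampling error uses the effective sample
size `n_eff = 4/(1/n_case + 1/n_control)` — with 287/360,143 this yields
se ~ 0.05, the realistic consequence of extreme case/control imbalance; a
naive total-n formula would understate it twenty-fold.

Horizontal pleiotropy adds `alpha ~ N(mu, sd^2)` to an affected fraction of
SNPs, applied as `sign(b) * alpha`: pleiotropic effects are expressed
relative to the exposure-increasing allele, the frame in which the Egger
intercept is defined.  (Applied in the raw allele frame, a directional mean
would be symmetrized away by the arbitrary allele orientation and no
intercept test could detect it.)  InSIDE holds by construction; an
`inside_violation` switch correlates alpha with instrument strength to
stress-test Egger.  Planted outliers add a fixed offset to the observed
outcome effect of chosen SNPs; palindromic A/T–C/G allele pairs are
assigned to a configurable fraction.

Chain simulations (exposure -> mediator -> outcome) give the exposure and
mediator disjoint instrument sets; mediator instruments use effect scale
0.5 (cytokine GWAS at n ~ 8,000 report instrument F in the hundreds,
implying per-allele effects of that size), and chain instrument magnitudes
are truncated below at 0.1 so every simulated instrument is a genuinely
ascertained locus.  Without the truncation, p-value selection conditions on
sampling noise for near-threshold effects (winner's curse) and attenuates
each leg by ~0.7% — a real property of p-value-selected instruments, but
one that would contaminate a benchmark of the decomposition itself.  The
generator therefore does **not** emulate winner's curse, LD structure,
sample overlap, allele-frequency mismatch between studies, or non-normal
effect distributions; passing tests say nothing about robustness to those
features of real data.

All randomness flows from one integer seed; fixed configuration implies
byte-identical output tables.

## Pipeline and reporting

For each exposure-outcome pair: select (with fallback), harmonize, fit the
four-method battery, run the sensitivity suite, remove PRESSO outliers and
re-fit once, then band the primary (IVW) p-value: `p < alpha/N` significant
(0.0125 for alpha = 0.05 over the N = 4 methods), `alpha/N <= p < alpha`
suggestive, else not significant.  Reverse MR is the same machinery with
roles swapped.  Reports are plain TSVs (results, sensitivity in the
published table layout, leave-one-out, MVMR, mediation) plus a JSON summary
and a JSONL audit stream of selection logs; nothing in the output depends
on wall-clock time, so a fixed configuration and seed reproduce
byte-identical reports.

## Validation studies and their problem sizes

The calibration module re-derives the estimators' frequency properties at
full study scale (sizes chosen to make Monte-Carlo error small relative to
the bands being checked, roughly two to three minutes end to end):

- IVW recovery: 500 replicates at theta = 0.2, J = 30 — mean estimate
  within 2 Monte-Carlo SEs of the truth; 95% CI coverage in [92%, 98%].
  Coverage sits near 93–95%: the fixed-effect IVW interval is known to be
  slightly anticonservative when the heterogeneity statistic fluctuates
  below its mean, and the auto switch only partly compensates.
- Type-I error: 1000 replicates at theta = 0 — rejection in [3%, 7%].
- Egger intercept: 500 replicates each — size ~5% under balanced
  pleiotropy (sd 0.05), power > 80% under directional mu = 0.1.
- MR-PRESSO: 200 runs at 1,000 simulation cycles (a deliberate scale-down
  from the conventional 3,000; resolution 1e-3 is ample for these checks) —
  global p uniform under the null (KS), detection of a planted
  10x-median-|by| outlier >= 95%.  The rate at which outlier removal moves
  the estimate toward the truth is ~75%, matching the influence model
  P(improve) = E[Phi(s/2 sigma)] with shift s = offset * bx_j / (J E[bx^2]):
  outliers planted on weak instruments are detectable but not influential,
  so their removal is a coin flip, while influential outliers are corrected
  essentially always.
- Mediation: 200 chain replicates — mediated estimate within 2 Monte-Carlo
  SEs of beta1*beta2 = 0.15; additivity exact in every run.
- Oracle agreement: 100 random instances — IVW/Egger vs numpy normal
  equations (< 1e-10), weighted median vs a cumulative-weight scan (exact),
  Q p-values vs the chi-square survival function (exact).

## Known limitations

- First-order ratio weights ignore exposure-side noise; with weak
  instruments (F near 10) estimates attenuate toward the null, as in any
  standard two-sample MR implementation.
- No LD-aware estimation: correlated instruments must be pruned (the
  package clumps; it does not model residual correlation).
- The distortion test's null (random same-size subset removal) is a
  resampling convention; alternatives exist and give similar answers only
  when outliers are few.
- Proportion-mediated intervals use the delta method and are unreliable
  when the total effect is small relative to its SE; the flags exist for
  exactly that reason.
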