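# Methods

This note documents the statistical model behind `beetox`, the choices
made where the methodology was genuinely open, and what the synthetic
bioassay generator does and does not emulate.

## Data model

Bioassays are stored per bee in right-censored long form: arm (control,
solvent control, fungicide-only, insecticide at one of several doses, or
insecticide + fixed fungicide co-dose), the last assessment time (hours
after the end of the exposure phase, on the fixed grid 3/24/48/72/96 h)
and a death indicator. Mortality is only read on the grid, so "time of
death" means "first assessment at which the bee was found dead"; bees
alive at 96 h are right-censored there. Per-bee body weights are not
recorded; a single species mean weight (honeybee 0.081 g, bumblebee
0.263 g, mason bee 0.092 g) converts per-bee doses to per-gram doses.

## Survival estimation and weighted log-rank tests

Kaplan–Meier curves use the standard product-limit estimator with deaths
preceding censorings at tied times. Two-sample comparisons use the
Fleming–Harrington G^ρ family with weights S̄(t⁻)^ρ, where S̄ is the
left limit of the pooled Kaplan–Meier estimate: ρ = 0 is the classic
log-rank, ρ = 1 the Peto–Peto test that up-weights early differences —
appropriate here because insecticide–fungicide synergism expresses early
after exposure. The statistic is kept in signed standardized form
(positive when the first group dies earlier) so the one-sided
"observed survival lower" alternative needed by the Bliss test is the
upper normal tail. Variances are hypergeometric, which handles the heavy
ties produced by the 5-point assessment grid; under exchangeability at
n = 30/arm the two-sided tests hold the 5 % level within Monte-Carlo
error for ρ ∈ {0, 1} (simulation test in the suite). The k-sample
omnibus test (ρ = 0, df = k−1) and the Holm-adjusted pairwise matrix
follow the standard workflow; pairwise tests are strictly two-sample per
pair.

## Bliss independence test

Under Bliss independence the expected mixture survival is the product of
the observed mono-treatment curves. Toxicants *decrease* survival, so the
synergism alternative is that the observed mixture curve lies *below*
the expectation (the direction is flipped relative to drug-efficacy
formulations of the same criterion).

A two-sample right-censored test needs a sample, not a curve, on the
expected side. The package realises the product curve by
**min-convolution**: if T_SUL ⊥ T_FLU then min(T_SUL, T_FLU) has survival
S_SUL·S_FLU, so pseudo-bees are built by pairing one resampled
observation from each mono arm and taking the minimum, a death iff the
minimum is attained by an actual death no later than the other
observation (ties resolve to death). The default pseudo-sample size is
10 × max(n_SUL, n_FLU); its Kaplan–Meier curve agrees with the product
curve to < 0.02 sup-distance at n_out = 10⁴ in the suite's checks.

Because the pseudo-sample reuses the mono-arm data, treating it as an
independent sample makes the asymptotic p-value optimistic: the
estimation error of the expected curve (driven by the ~60 mono-arm bees)
is comparable to the mixture arm's own sampling noise but is ignored by
the hypergeometric variance. Measured type-I error of the asymptotic
test is ~12 % at nominal 5 % under the generator's null. The
**bootstrap calibration** (the recommended mode, used in the calibration
tests) rebuilds the null distribution with both error sources in place:
each replicate pairs (a) a mixture-sized min-convolution draw from the
original mono arms — an independent sample from the estimated product
law — with (b) an n_out-sized draw from bootstrap-resampled mono arms,
which carries the expected-curve estimation error. A plain label
permutation was considered and rejected: permuting dependent
pseudo-observations neither respects the resampling structure nor
captures the estimation error (and a naive bootstrap building both
samples from the same resampled arms cancels exactly the error it should
propagate — measured type-I stayed ~12 %). With the corrected null the
measured type-I error is 3–4 % at nominal 5 % (500 replicates) and power
against a true synergism ratio of 3 at an intermediate dose exceeds 95 %
at n = 30/arm. Tests are per dose; no pooling across doses.

## Probit dose–response and LD50

At each assessment time, cumulative mortality per dose group follows

    P(dead | d) = c + (1 − c) · Φ(α + β · log10 d)

with c the natural (background) mortality. The fit is full maximum
likelihood (Nelder–Mead, then BFGS polish; covariance from the observed
information by central finite differences). Log base 10 is used for
doses; LD50 = 10^(−α/β) is base-invariant, and with the c-adjusted model
the LD50 is where the *treatment-induced* (Abbott-corrected) mortality
reaches one half, which is −α/β regardless of c.

**Natural response.** When a control group is supplied, c is estimated
jointly (logit-parameterised) rather than only when control deaths were
observed. The narrower rule is fragile: a clean control (a coin flip at
n = 30 with ~2 % background mortality) would force c = 0, and the
background deaths present at the low doses then explode the Pearson
statistic (observed ≥ 1 vs expected ≈ 0), inflate the covariance through
the heterogeneity factor and spuriously fail the slope gate. Joint
estimation lets c shrink to ~0 when the control is genuinely clean.
Modes `fixed_zero` and `estimate` remain available.

**Heterogeneity.** When the Pearson goodness-of-fit p < 0.15 and
χ²/df > 1, the covariance is inflated by χ²/df and t-based critical
values (df = groups − parameters) replace normal ones — the documented
behaviour of the classic probit implementations.

**Determinability.** An LD50 is reported as non-determinable when the
slope is non-positive, when the Wald slope test is not significant at
the 5 % level (mirroring dose-response tables that leave such cells
blank), or when Fieller's g ≥ 1 so no finite interval exists.
Non-determinable cells propagate as explicit missing values, never
zeros.

**Fieller limits.** The 95 % CI for log10 LD50 is the solution set of
(α + βx)² ≤ t²·Var(α̂ + β̂x) using the (possibly inflated) covariance,
back-transformed to dose scale. In the recovery study (mason-bee-like
scenario, 200 replicates at n = 30/group) the median |log10 bias| of the
24 h LD50 is ~0.03 and Fieller coverage ~97 %.

**Controls per arm.** The solvent control backs the insecticide-alone
fits; the fungicide-only arm backs the mixture fits, since its co-dose
is present in every mixture bee. Mixture LD50s are parameterised by the
insecticide dose at the fixed co-dose.

## Ratio test, toxic units, MDR

The synergism ratio SR = LD50_alone / LD50_mix gets a normal-theory CI
on the log10 scale, log10 SR ± z·√(se²_alone + se²_mix). Each
se(log10 LD50) is taken as the half-width of that fit's Fieller interval
divided by its critical value rather than the raw delta-method SE: the
delta SE underestimates the finite-sample spread at n = 30/dose
(standardized errors have SD ≈ 1.08), giving ~93 % coverage of a true
unit ratio, while the Fieller-implied SE restores ~94 % (500 simulated
pairs; the suite asserts 95 ± 2 %). Synergism is declared when SR > 1
with the CI excluding 1; an antagonism flag (SR < 1, upper limit < 1) is
also exposed.

Toxic units orient as TU_SUL = LD50_mix / LD50_alone (the mixture's
insecticide content at its LD50 as a fraction of the solo LD50) and
TU_FLU = co-dose / reference fungicide LD50 (1.2/110.9 µg = 0.0108,
anchored to the honey-bee value for all species because no
species-specific fungicide LD50 exists; configurable). MDR =
1/(TU_SUL + TU_FLU), classified synergism above 1.25, antagonism below
0.83, additivity between (boundary values inclusive of additivity). With
TU_FLU = 0, MDR reduces exactly to SR. At n = 30/dose the log-ratio SD
(~0.07) places these thresholds only ~1.2 SDs from 1, so under true
independent action the point-estimate MDR classifies "additivity" in
roughly 80–88 % of replicates — a precision limit of the thresholds at
this group size, not a defect of the arithmetic.

The interspecies sensitivity ratio divides the minima (over assessment
times) of two species' determinable LD50s, per gram by default. The
nectar exposure calculator converts a residue concentration (mg a.i./kg)
times consumption (default 80 mg, one hour of foraging) into ng/bee and
flags doses at or above a supplied LD50.

## Synthetic bioassay generator

Each bee draws a single latent tolerance quantile u; at time t and dose
d it is dead from treatment iff u < Φ(slope·(log10 d − log10 LD50(t))),
with LD50(t) = LD50₉₆·g(t), g non-increasing to 1 at the horizon. The
single-latent construction makes death status monotone in time and makes
the cross-sectional probit the *exact* generating law at every
assessment time — a per-interval hazard model was rejected because it
lacks that property. Mixture arms divide LD50(t) by the true synergism
ratio. Background mortality strikes each inter-assessment interval
independently with probability 0.005 (≈ 2.5 % cumulative, well under the
10 % validity ceiling of acute-test guidelines), before the treatment
check, in all arms. Defaults: n = 30 bees/group (near typical cage
sizes), seven-dose factor-2 series 2.75–176 ng/bee, co-dose 1.2 µg/bee.

Reference scenarios: mason-bee-like (LD50₉₆ = 5.9 ng/bee, strong early
decay, slope 2.5/log10), bumblebee-like (83.5 ng/bee, plateau after
24 h, slope 4), honeybee-like (30 ng/bee, shallow slope 1). Slopes and
the honeybee LD50 are package choices of plausible magnitudes; the other
anchors and decay shapes follow the published per-time LD50 patterns.

The generator treats bees as independent: no cage effects, no feeding
variance, no body-weight covariates, no emergence-time heterogeneity.
Passing calibration tests therefore demonstrate correctness of the
estimators under the assumed tolerance model, not robustness to the
overdispersion real cage designs can add.

## Numerical conventions and problem sizes

Probabilities are clipped at 1e-12 in likelihoods; fitted p-values are
reported exactly and floored only by machine precision. Simulation-based
checks in the test suite use 100–500 replicates at n = 30/group (probit
recovery 200, Bliss type-I 500 with 200 bootstrap draws, ratio coverage
500 pairs, power 200), sizes at which the whole suite completes in a few
minutes on one core. All randomness flows through explicit integer
seeds; identical seeds reproduce byte-identical datasets and reports.

## Known limitations

* The Bliss bootstrap calibration conditions on the observed mono arms;
  it is consistent but, like all resampling calibrations, slightly
  conservative at these group sizes (measured 3–4 % at nominal 5 %).
* The slope-significance gate makes LD50 availability data-dependent;
  downstream summaries propagate missingness rather than imputing.
* MDR classification uses LD50 point estimates only (as the convention
  prescribes); its misclassification rate under true additivity is set
  by the LD50 precision, see above.
* Grid censoring discards within-interval timing; all methods treat the
  grid as exact observation times, matching how such assays are read.
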