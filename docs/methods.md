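# Methods

## The problem being modelled

A pathology department switches abruptly from glass slides to digital
sign-out. To measure what that does to diagnostic quality, a panel of 17
raters (grouped into four career levels: resident, junior, expert, senior)
re-reads 25 archival cases on screen, answering up to five diagnostic
questions per case; each answer is scored correct or erroneous against the
original microscope diagnosis. The quantities of interest are the marginal
error rates (by rater, career level, task, specimen type, subspecialty) and
a model-based decomposition of those errors into additive rater/task/case
effects.

## Study design and conditional eligibility

The design is factorial with conditional question eligibility:

* 25 cases: 10 breast, 5 urology, 10 gastrointestinal; 14 biopsies, 11
  surgical specimens; 8 non-tumoral, 7 benign, 10 malignant (grades split
  5/5 between grade 2 and grade 3).
* Five question categories: (1) neoplastic or not, (2) malignant or benign,
  (3) histopathological diagnosis, (4) histotype, (5) grade. Categories 1
  and 3 apply to every case, category 2 only to neoplastic cases,
  categories 4–5 only to malignant ones.

The naive reading (category 2 on all 17 tumoral cases, 4 and 5 on all 10
malignant ones) gives 87 questions per rater and 1479 total items, which
contradicts the study's printed totals of 85 and 1445. The generator's
default eligibility — category 2 on 16 of 17 tumoral cases, category 5 on
9 of 10 malignant ones — is the feasible assignment that reproduces the
printed totals while keeping each category's capacity (17 × eligible
cases) at or above its answered count. Which specific cases lacked which
questions is not recoverable from the published counts; the canonical
25-case layout in `synthetic_study.table1_design` is one verified-feasible
choice, not the study's actual one.

## Missingness

100 of 1445 items are unanswered. No mechanism is documented, so
missingness is modelled as completely at random with default rate
100/1445 ≈ 0.069. Everything downstream uses complete cases only: every
denominator is the number of *answered* items, matching the published
denominator of 1345.

## Reconstruction from marginal tables

Item-level data are not published; five marginal tables (counts of tasks
and errors by rater, level, category, specimen, subspecialty) are. The
reconstruction proceeds in two seeded subset-selection problems over the
design's 1445 eligible (rater, case, question) triples: first choose the
100 missing items so the answered counts hit all four independent margins
exactly, then choose the 117 error flags among answered items the same
way. Each selection uses a greedy seeded pass followed by targeted local
search (add/remove/swap moves that never increase the total L1 margin
violation, with sideways moves to escape plateaus). The search fails
loudly if the reference tables are internally inconsistent, if the
design's eligibility cannot carry the counts, or if the iteration cap
(default 200 000 moves; in practice a few hundred suffice) is reached.

The career-level membership of each rater is likewise not published.
Exhaustive search over the published per-rater and per-level counts shows
exactly four compatible assignments; the canonical design fixes one of
them. Reconstructed datasets are non-unique by construction — any dataset
passing marginal validation is equally compatible with the published
tables — and two seeds give two different, equally valid datasets.

## Descriptive conventions

* Rates are kept unrounded internally; group summaries (median, quartiles)
  are computed on unrounded rates by linear interpolation at position
  1 + (n−1)p (numpy's default, R's quantile type 7). With this convention
  the per-rater rates give median 0.07 and IQR 0.04–0.11 and the per-level
  rates median 0.07 with IQR 0.07–0.10 after display rounding.
* Display rounding is half-away-from-zero to 2 decimals, applied only at
  presentation (26/81 = 0.3210 → 0.32).
* An empty cross-tabulation cell reports an undefined rate (NaN), never 0.
* The published narrative quotes a grading error of "23%" where the table's
  counts give 27/147 = 0.184; the count table is treated as authoritative.

## The hierarchical error model

For each answered item *i*, the error indicator is Bernoulli:

    W_i ~ Bernoulli(p_i)
    logit(p_i) = α_PID[i] + β_LEVEL[i] + γ_CATEGORY[i] + δ_SPECIMEN[i] + ε_SPECIALTY[i]

with varying intercepts per cluster:

    α_j ~ Normal(ᾱ, σ_α)   j = 1..17   (raters, partially pooled)
    β_j ~ Normal(0, σ_β)   j = 1..4    (career levels)
    γ_j ~ Normal(0, σ_γ)   j = 1..5    (task categories)
    δ_j ~ Normal(0, σ_δ)   j = 1..2    (specimen types)
    ε_j ~ Normal(0, σ_ε)   j = 1..3    (subspecialties)

    ᾱ ~ Normal(0, 1.5)      σ_* ~ Exponential(1)

The Normal(0, 1.5) hyperprior is weakly regularizing on the probability
scale (its pushforward through the inverse logit is nearly flat); the
Exponential(1) scale priors are the maximum-entropy choice for a
nonnegative scale with unit mean.

**Identifiability.** Each rater has exactly one career level, and the grand
level of the linear predictor can be shifted between ᾱ and the
(soft-zero-centred) means of the other clusters without changing the
likelihood. Only the priors identify the split. Two practical
consequences, both verified empirically: the posterior SD of ᾱ plateaus at
the width of that prior ridge (≈0.8–1.0 here) rather than shrinking with
more data, and the posterior mean of ᾱ sits noticeably above the pooled
logit of the raw error rate (≈ −1.9 versus logit(117/1345) ≈ −2.35),
because the weak hyperprior lets the zero-centred clusters absorb part of
the negative grand level. Identified functionals (for example the
item-averaged linear predictor, or any cell probability) do concentrate
with data, and the property suite tests concentration on those.

## Posterior computation

The posterior is sampled with the package's own Hamiltonian Monte Carlo
engine (`dpconcord._hmc`): leapfrog integration with a diagonal mass
matrix, dual-averaging step-size adaptation to a target acceptance rate of
0.95, windowed (Stan-style doubling schedule) estimation of the metric
during warmup, and trajectory lengths jittered ±20% around an integration
time of 1.5 to avoid resonance. A transition whose Hamiltonian error
exceeds 1000 counts as divergent and is rejected. Defaults: 4 chains,
1000 warmup + 1000 retained iterations each.

Sampling uses unconstrained coordinates: scales enter as log σ with the
Exponential prior's Jacobian term, and the non-centred parametrization
(α_j = ᾱ + σ_α·z_j, z standard normal; analogously for the zero-centred
clusters) is the default, with the centred form retained for cross-checks.
The likelihood is evaluated on binomial-aggregated cells (items sharing a
rater × category × specimen × subspecialty combination), which is exact —
the binomial coefficient does not depend on the parameters — and an order
of magnitude cheaper than per-item evaluation. The linear predictor is
clipped at ±500 inside the sampler closure only, where the Bernoulli terms
are numerically saturated anyway; this prevents inf·0 artifacts on wildly
divergent proposals without affecting the typical set.

Engine correctness is established by three independent routes in the test
suite: prior-only sampling recovers the analytic prior moments; centred
and non-centred fits agree within Monte Carlo error; and posterior means
agree with an independent affine-invariant ensemble sampler (emcee) on the
same log-density. The log posterior itself is checked against a naive
per-item, per-density implementation to 1e-10 relative error.

Convergence reporting: split-R̂ and bulk effective sample size per scalar
parameter (via ArviZ), divergence counts, and acceptance rates. Any R̂
above 1.01 or any divergence is attached to the result as a warning, never
silenced.

## Predictive simulation

*Prior predictive*: hyperparameters and effects are drawn from the priors
and a full study is simulated per draw; the resulting distribution of
overall error rates spans most of (0, 1), confirming the priors are weakly
regularizing rather than informative.

*Posterior predictive ("average pathologist")*: per posterior draw the
error probability of an average rater at career level ℓ is
inverse-logit(a + β_ℓ), with task, specimen and subspecialty effects set
to zero — the case mix is a property of this study's non-random case
selection, not of the rater. Two modes are offered because the published
description does not fix one: `grand_mean` uses a = ᾱ directly;
`new_pathologist` (the default) draws a ~ Normal(ᾱ, σ_α) per draw,
propagating between-rater spread, and therefore yields intervals at least
as wide. Intervals are highest-posterior-density (shortest interval
containing ⌈mass·n⌉ sorted draws, ties broken to the lowest start), at
89% by default. The fresh-rater noise is paired with draws in a canonical
sort order so summaries are invariant to draw order.

## Survey aggregation

The exit survey has 17 Likert questions (1–5) in three fields. The
per-field split of 4 (attitude), 7 (confidence), 6 (satisfaction)
questions is inferred from the published high-score denominators 68, 119
and 102 divided by 17 raters — exact divisibility makes this compelling,
but it is an inference, not a documented fact. The synthesizer constructs
response sets hitting requested high-score counts exactly; aggregation
reports per-score proportions and the 4-or-5 proportion with numerator and
denominator. Display rounding follows the reported precision (one decimal
or integer percent).

## Problem sizes and test budgets

The test suite fits the full model once at the default 4 × 1000/1000
configuration on the 1345-item reconstruction (~1 minute), runs a
parameter-recovery fit on a 10× rater panel (~13 450 items, ~6 minutes),
and keeps every other fit at toy scale (hundreds of items, 2 chains,
several hundred iterations) — sizes chosen so the complete suite runs in
roughly ten minutes on one CPU while still exercising the full-scale
configuration once.

## Known limitations

* The reconstruction matches the five published marginal tables but cannot
  recover the true item-level data; quantities that depend on higher-order
  interactions (for example rater × task cells) vary between seeds.
* Missingness is completely at random by assumption; the per-rater missing
  counts are matched, but any informative skipping in the real study is
  not modelled.
* No rater learning over time, case-difficulty covariates, correlation
  between clusterings, or model comparison (WAIC/LOO) — out of scope.
* The grade attribute of malignant cases and the specific case-eligibility
  layout are synthetic choices constrained, but not determined, by the
  published counts.
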