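# dpconcord

Concordance analytics for digital-pathology validation studies: when a
department moves from glass slides to digital sign-out, a panel of raters
re-reads a set of archival cases on screen and every answer is scored
against the original microscope diagnosis. `dpconcord` turns that study
design into a tested pipeline for biostatisticians: descriptive error-rate
tables, a generative model of such studies, and a hierarchical Bayesian
decomposition of the errors.

The package emulates a specific design — 17 raters in 4 career levels
(resident, junior, expert, senior), 25 cases in 3 subspecialties and 2
specimen types, 5 conditionally-eligible diagnostic questions per case,
1445 items of which ~7% go unanswered — but every composition count is
configurable.

## The model

Each answered item *i* is a Bernoulli trial for the error indicator
`W_i ~ Bernoulli(p_i)` with additive varying intercepts on the log-odds
scale:

```
logit(p_i) = α_PID[i] + β_LEVEL[i] + γ_CATEGORY[i] + δ_SPECIMEN[i] + ε_SPECIALTY[i]

α_j ~ Normal(ᾱ, σ_α)        (17 raters, partially pooled)
β_j ~ Normal(0, σ_β)        (4 career levels)
γ_j ~ Normal(0, σ_γ)        (5 diagnostic tasks)
δ_j ~ Normal(0, σ_δ)        (2 specimen types)
ε_j ~ Normal(0, σ_ε)        (3 subspecialties)

ᾱ ~ Normal(0, 1.5)          σ_* ~ Exponential(1)
```

The posterior is sampled by the package's own adaptive Hamiltonian Monte
Carlo engine (non-centred parametrization by default, divergence
detection, split-R̂/ESS diagnostics). See `docs/methods.md` for the full
account, including the identifiability caveat on ᾱ and how the sampler is
validated.

## Worked example

Marginal error tables from the packaged item-level fixture (a seeded
reconstruction whose five marginal tables match the published study
counts exactly):

```
$ dpconcord describe
grouping,group,n_tasks,n_errors,rate
pathologist,P1,84,5,0.06
pathologist,P2,78,4,0.05
...
total,total,1345,117,0.09
# pathologist: median 0.07 (IQR 0.04-0.11) over 17 groups
# level: median 0.07 (IQR 0.07-0.10) over 4 groups
```

Each row is one group's answered-item count, error count, and error rate
(117/1345 ≈ 9% overall; the per-rater spread 0.01–0.32 collapses to
0.07–0.10 across career levels). Fitting the model and summarising the
posterior:

```python
from dpconcord import FitConfig, fit, table1_design, table1_items

design = table1_design()
posterior = fit(table1_items(), design, FitConfig(seed=7))
alpha_bar = posterior.flat("alpha_bar")
print(round(alpha_bar.mean(), 2), round((alpha_bar < 0).mean(), 2))
print(posterior.n_divergent, round(posterior.max_rhat, 3))
```

prints (about one minute on one CPU):

```
-1.89 0.96
0 1.006
```

The grand-mean rater intercept ᾱ is about −1.9 on the logit scale with
96% of its mass below zero — the average rater is far more likely to be
right than wrong — with zero divergent transitions and all R̂ ≤ 1.01.
Survey aggregation:

```
$ dpconcord survey --seed 0 --out survey.csv
attitude: very good 44/68 = 64.7%
confidence: very good 75/119 = 63.0%
satisfaction: very good 56/102 = 54.9%
```

Other subcommands: `simulate` (generative draws from configurable truth),
`reconstruct` (item-level data matching marginal tables), `fit`,
`predict` (average-rater error by career level with 89% HPDI), and `run`
(the whole pipeline with a reproducibility manifest).

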