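# relistab

**Test–retest reliability and sample-size stability of reversal-learning
measures.**

`relistab` is a research pipeline for a question that test–retest studies of
learning and decision-making keep running into: *how many subjects are needed
before estimates of reliability — and of the variance components underneath
them — can be trusted?* It targets the two-session probabilistic
reversal-learning task, where behavioural summaries (accuracy, perseveration,
win-stay/lose-shift, reaction times) and reinforcement-learning model
parameters (learning rates α, inverse temperatures β, reinforcement
sensitivities ρ) are the measures of interest.

The package is aimed at researchers in computational psychiatry and
individual-differences work who need to (a) quantify reliability by variance
decomposition rather than a single intraclass correlation, and (b) plan
sample sizes for reliability studies using synthetic-data simulation.

## The model and statistics at its core

**Variance decomposition and ICC(A,1).** For an *n* subjects × *k* = 2
sessions table *X*, the two-way ANOVA mean squares are

```
Between = k/(n−1) · Σᵢ (x̄ᵢ − x̄)²                       (MSr)
Within  = n/(k−1) · Σⱼ (x̄ⱼ − x̄)²                       (MSc)
Error   = (SS − (n−1)·MSr − (k−1)·MSc) / ((n−1)(k−1))   (MSe)
```

The within-subject component is corrected by *k/n* and the three components
are normalised to proportions summing to one. The intraclass correlation for
two-way, absolute-agreement, single measurements is

```
ICC(A,1) = (MSr − MSe) / (MSr + (k−1)·MSe + (k/n)·(MSc − MSe))
```

interpreted as poor (< 0.4), fair, good, or excellent (≥ 0.75).

**Regression-based synthesis.** A measure's two-session structure is
captured by `X₂ = β₀ + β₁·X₁ + e`: the session-1 marginal and the residual
distribution are each fitted from a library of scipy families by minimising
the sum of squared errors against a Freedman–Diaconis histogram density, and
synthetic datasets draw `X₁ₛ` and `eₛ` to produce
`X₂ₛ = β₀ + β₁·X₁ₛ + eₛ`. A noise variant z-scores both sessions, adds
Normal(0, s) draws to session 2, and reverses the z-scoring.

**Point of stability.** Variance proportions are recomputed on nested
subject subsets from 10 to 300. Given a ground truth *g* and a corridor of
stability *g ± w*, the point of stability (PoS) of one trajectory is the
smallest sample size from which the estimate never again leaves the
corridor (300 if it never settles, 10 if it never deviates). Percentiles
(80/90/95) of the PoS distribution across synthetic datasets give the
critical sample size for a chosen precision and confidence.

**Reinforcement-learning models.** Delta-rule value learning
`V ← V + α(λ′ − V)` with two families of choice rules (softmax-β and
reinforcement-sensitivity ρ, each with optional win/loss splits), optional
dual (counterfactual) updating with discount κ, fitted by ML, MAP with
uninformative priors (MAP0), or expectation–maximisation with an empirical
multivariate-Gaussian group prior; models are compared by the integrated
BIC (iBIC).

Because human data cannot ship with the package, a first-class simulator
generates the task schedule (150 trials, 9 reversals every 15 ± 3 trials,
75 % reward pseudorandomised over blocks of four) and heterogeneous agent
cohorts with lognormal reaction times, post-loss slowing, lapses and
session-2 improvement, plus the standard data-quality screens (exact
binomial chance test, careless-responding flags).

## Worked example

```python
import numpy as np
from relistab import task, behaviour, reliability, synth, stability

# simulate a two-session cohort of 100 reversal-learning agents
trials = task.simulate_cohort(task.PopulationSpec(), 100,
                              rng=np.random.default_rng(404))

# per-subject-session accuracy, raw means
acc = behaviour.estimate_measures(trials, "accuracy", "mean")
wide = acc.pivot(index="subject_id", columns="session", values="value")
X = wide.to_numpy()

print(reliability.variance_components(X).proportions)
print(reliability.icc_a1(X).icc_a1)

# fit the synthetic generator and sweep sample sizes
spec = synth.build_synth_spec(X[:, 0], X[:, 1], measure="accuracy",
                              n=300, n_datasets=100, seed=29)
ens = synth.generate_ensemble(spec)
g = dict(zip(("between", "within", "error"),
             reliability.variance_components(X).proportions))
trajs = stability.ensemble_trajectories(ens)
pos = stability.pos_table(trajs, g, widths=(0.05,))
print(stability.critical_n(pos["pos"], 80))
```

Running this prints (seed-for-seed):

```
(0.6838, 0.0071, 0.309)
0.3771
146.2
```

meaning ~68 % of this cohort's accuracy variance is between-subject, yet
the absolute-agreement ICC is still poor (0.38, pulled down by the
session-2 practice gain and trial-level noise), and with a corridor
half-width of 0.05 the 80th percentile of the PoS distribution over 100
synthetic datasets is ≈ 146 subjects — variance proportions estimated from
smaller samples have not yet stabilised.

The same pipeline runs end-to-end from the shell:

```bash
relistab run-all --config config.yaml --seed 11 --outdir runs/demo
```

with subcommands `simulate`, `screen`, `measures`, `fit`, `reliability`,
`synth`, `stability`, `report` for stage-wise execution.

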