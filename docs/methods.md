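# Methods

This note documents the models and procedures implemented in `relistab`,
the assumptions behind them, the defaults and why they were chosen, and the
limits of what the synthetic-data machinery can show.

## Task simulator

The simulated task is a two-choice probabilistic reversal-learning
paradigm: 150 trials, one of two stimuli "correct" at any moment, the
correct stimulus rewarded on 75 % of trials and punished otherwise (the
incorrect stimulus carries the inverse probabilities), nine reversals of
the stimulus–outcome mapping spaced 15 ± up to 3 trials apart (uniform over
the integers 12–18), and a 2,000-ms response window.

Design choices where the task description leaves room:

- **Reversal placement.** All nine inter-reversal gaps are drawn jointly
  and the vector is redrawn until the last reversal falls inside the 150
  trials. This keeps each gap marginally close to uniform; the acceptance
  script measures the residual truncation bias (the grand mean gap is
  ≈ 14.99 rather than 15 exactly, well inside Monte-Carlo noise at 5,000
  schedules).
- **Outcome pseudorandomisation.** The 75 % assignment is made exactly true
  over blocks of four trials *aligned to absolute trial index* (1–4, 5–8,
  …), independent of reversal positions — the simplest reading of
  contiguous four-trial blocks. The final partial block (trials 149–150)
  truncates a freshly shuffled full-block pattern. Outcomes are
  pre-assigned per stimulus *role* (correct/incorrect), so what a subject
  receives depends only on which role they chose.
- **Gap endpoints.** "Up to 3" is taken as inclusive, i.e. gaps of exactly
  12 or 18 trials can occur.

## Agents

Agents are the package's reinforcement-learning observers run generatively.
Two families:

- **softmax-β**: values learned from raw ±1 outcomes; choice via a softmax
  with inverse temperature β, optionally split into β_win/β_loss selected
  by the valence of the previous trial's feedback (the first trial, or a
  trial following a missing outcome, uses the mean of the two — an
  assumption isolated in the likelihood core).
- **reinforcement-ρ**: unit-temperature softmax; outcomes scaled by
  sensitivities before updating, λ′ = ρ_win·λ for wins and ρ_loss·λ for
  losses. Because updates drive V toward λ′ geometrically, |V| can never
  exceed max(|ρ_win|, |ρ_loss|), which bounds the value difference and
  hence places a floor under choice stochasticity.

  One parameterisation ambiguity deserves a note: published parameter
  tables for this family report the loss sensitivity natively negative,
  which under the multiplicative convention λ′ = ρ_loss·λ would make
  losses *appetitive*. The multiplicative convention is implemented as
  stated (identity transform, so negative natives remain representable);
  the default simulated population uses ρ_loss > 0 so that losses are
  aversive and the lose-shift rate exceeds the win-shift rate, as observed
  empirically.

Common machinery: values start at V₀ = (0, 0) with no free initial-value
parameter; single or dual (win/loss) learning rates selected by the
factual outcome's valence; *dual-update* variants also update the unchosen
action toward κ·(−λ′) with the same learning rate (κ = 1 unless the model
carries a free discount weight). Missing trials are skipped in the
likelihood and the values carried forward. The exact counterfactual form
is a documented choice confined to one function so alternatives can be
plugged in.

The generative reaction-time model — needed because value-based observers
have no latencies — is lognormal on the log-ms scale (subject-level
`rt_mu`, `rt_sigma`), an additive post-loss slowing `rt_loss_shift`
(default 40 ms, matching the direction and order of magnitude of empirical
previous-feedback effects), truncation at the 2,000-ms window, and an
optional lapse probability producing missing responses. Session-2
improvement is an additive drift (default +0.1) on the *transformed*
parameters, which nudges accuracy up between sessions without changing the
parameterisation.

Default population heterogeneity (Gaussians on the unconstrained scale:
logit for α and κ, log for β, identity for ρ): α ~ logit-N(0.9, 0.5²)
(median α ≈ 0.71), ρ_win ~ N(2.0, 0.6²), ρ_loss ~ N(0.9, 0.35²). These
centre the cohort near published group-level estimates for the winning
dual-update model while keeping enough spread for between-subject analyses
to have signal.

## Screens

A subject-session is kept only when the count of best-stimulus choices
among valid trials is significantly *above* chance under a one-sided exact
binomial test (p < 0.05 by default) — anyone not demonstrably above chance
is excluded, which operationalises "at or below chance" conservatively.
Careless/insufficient-effort flags mark five consecutive missing responses
(the live task would have aborted) and more than 5 % missing overall.

## Behavioural measures

Accuracy, perseveration, stay (overall and split by previous win/loss) and
reaction time (overall, split, and win − loss difference). Perseveration
is operationalised as: after each reversal, once the subject has incurred
two losses (not necessarily consecutive) from choosing the now-worst
stimulus, subsequent trials up to the next reversal are *eligible*, and
the measure is worst-stimulus choices over eligible trials pooled across
reversals. Stay indicators require both members of the consecutive pair to
be valid; a missing trial breaks the pair.

Three estimation methods: `mean` (raw proportions/means), `separate`
(per-session mixed model, subject random intercept) and `joint` (one model
over both sessions with a session fixed effect, subject random intercept
and random session slope — the random-slope structure is a design choice).
Binary measures use a variational-Bayes mixed logistic model, linear
measures a standard linear mixed model; subject-session values are the
inverse-link of the subject-specific (shrunken, conditional) linear
predictor. Non-convergence falls back to raw means with a warning. The
win − loss RT difference under model-based methods is the difference of
the modelled win and loss estimates.

## Model fitting

Per subject-session likelihood optimisation runs on the unconstrained
scale (L-BFGS-B, multistart, bounds ±20 to keep transforms finite). MAP0
adds a Normal(0, 10²) prior per unconstrained parameter. EM alternates
per-session MAP fits under the current Gaussian group prior (E-step, with
Laplace covariances from a finite-difference Hessian whose eigenvalues are
floored at 1e-4) with a full empirical-Bayes moment update of the prior
mean and covariance (M-step, ridge floor 1e-6 on the covariance
diagonal; non-positive-definite covariances are eigenvalue-repaired with a
warning). Convergence is declared when the largest change in any prior
parameter falls below 1e-3; at least 10 subject-sessions are required.

iBIC is computed by simple Monte Carlo: K prior draws (default 2,000),
per-subject log-mean-exp of the data likelihood, times −2, plus the number
of prior hyperparameters (means + unique covariance entries) times the log
of the total valid-trial count. Ties in the model grid are broken by fewer
parameters. The likelihood recursion is compiled with numba when present
(a pure-NumPy fallback is tested against it); the iBIC sampler vectorises
the recursion across prior draws.

## Reliability

Variance components follow the two-way ANOVA identities given in the
README; because the decomposition is exact, the error mean square is
non-negative up to rounding, and the rounding-level negatives that appear
in degenerate tables (e.g. duplicated sessions) are floored at zero with a
warning before normalisation. ICC(A,1) confidence intervals use the
standard F-approximation with Satterthwaite degrees of freedom (verified
against an independent implementation). Split-half reliability uses random
permutation splits (100 by default, a choice — odd/even splitting is a
trivial variant) with Spearman–Brown correction averaged across splits.

## Synthetic two-session generation

The distribution selector fits each candidate scipy family by its own MLE,
scores it by the sum of squared errors between the fitted density and a
Freedman–Diaconis histogram density (density, not counts), and keeps the
minimum. The default candidate list is a fast, well-behaved subset of 15
families; a broad list of ~75 is available (`CANDIDATES_FULL`) and
excludes families whose MLE is pathologically slow or unstable on small
samples, since a single such fit can dominate the entire pipeline's run
time. Note that flexible families that contain a simpler one as a special
case (e.g. skew-normal ⊃ normal) can win by an SSE hair; the selected
density, not the family label, is what the generator consumes.

Residuals are fitted raw (not standardised). Synthetic values are *not*
clipped to a proportion's [0, 1] range: the variance machinery is
unaffected and clipping would distort the fitted marginals. Noise
injection reverses the z-score with each session's own pre-noise moments
(sample SD, ddof = 1); with noise_sd = 0 the transform is an exact
identity. One master seed spawns per-dataset child seeds through NumPy's
`SeedSequence`, so ensembles are reproducible and datasets mutually
independent.

## Stability sweep

Trajectories use *nested* subject subsets (the first n subjects of each
dataset), which makes the PoS scan well defined per dataset; independent
resampling per n would decouple successive estimates and inflate PoS.
The grid is 10–300 in steps of 1 by default and fully configurable for
scaled-down runs. Critical sample sizes use the inclusive
linear-interpolation quantile, chosen because summary tables of critical N
are naturally non-integer under interpolation. Spearman correlations
between components and ICC are Bonferroni-corrected over the entire
(measure × component × n) sweep.

## Problem sizes used in the tests and acceptance script

The automated checks run the pipeline at desk scale as the package's own
verification conditions: cohorts of 20–100 agents, ensembles of 100–200
datasets of n = 300 (against 1,000 in a full study), 20 replicates for
model recovery, and 5,000 schedules for the inter-reversal-interval check.
Full-scale runs (1,000 datasets per measure and noise level) use the same
code paths through the CLI.

## What the synthetic data does and does not show

The agent cohort emulates the structural features of real two-session
data: between-subject parameter heterogeneity, stable traits across
sessions with a small practice gain, post-loss slowing, lose-shift
dominance, lapses, and chance-level outliers. It does not emulate
context-driven within-subject state changes (mood, fatigue), RT
distributions beyond a shifted lognormal, or model misspecification
(subjects whose generative process is outside the fitted family).
Passing tests therefore demonstrate that the estimators and the
stability machinery behave correctly *under the model class*, not that
any particular human dataset is reliable.

## Known limitations

- Mixed logistic models use a variational approximation; its shrinkage is
  close to, but not identical with, exact-likelihood conditional modes.
- The EM Laplace approximation assumes a locally quadratic posterior;
  heavy-tailed subject posteriors (e.g. near-deterministic choosers) are
  summarised optimistically, mitigated by the curvature floor.
- iBIC is a sampled quantity; its Monte-Carlo error shrinks as 1/√K and
  repeat-run agreement is tested, but model comparisons within a few
  units of each other should be treated as ties.
- Measures are synthesised independently of one another (no copulas), so
  cross-measure correlation structure is not preserved in ensembles.
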