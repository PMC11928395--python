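"""Reinforcement-learning model family for two-choice reversal learning.

Two model families are supported. The *softmax-beta* family scales the
softmax with an inverse temperature ``beta`` (optionally split by the
valence of the previous trial's feedback), learning from raw ±1 outcomes.
The *reinforcement-rho* family uses a unit-temperature softmax and instead
scales the outcomes by reinforcement sensitivities ``rho`` (optionally split
by outcome valence), which bounds the attainable value difference and hence
places a lower bound on choice stochasticity.

Both families update the expected value ``V`` of the chosen action with a
delta rule ``V <- V + alpha * (lambda' - V)`` where ``lambda'`` is the
(possibly sensitivity-scaled) outcome; *dual-update* variants additionally
update the unchosen action toward the discounted inverse outcome
``kappa * (-lambda')``.

Fitting is per subject-session by maximum likelihood (ML), MAP with a broad
Gaussian prior on the unconstrained scale (MAP0), or expectation-maximisation
with an empirical multivariate-Gaussian group prior (EM); EM fits are scored
with the integrated BIC (iBIC), a sampled marginal likelihood penalised by
the number of group-prior parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "ModelSpec",
    "GroupPrior",
    "FitBundle",
    "MODEL_GRID_RHO",
    "MODEL_GRID_BETA",
    "negative_log_likelihood",
    "loglik_batch",
    "simulate_choices",
    "fit_ml",
    "fit_map0",
    "fit_em",
    "ibic",
    "model_grid",
    "to_unconstrained",
    "to_native",
]

# covariance ridge floor used in the EM M-step
COV_RIDGE = 1e-6
# default breadth of the MAP0 prior on the unconstrained scale
MAP0_PRIOR_SD = 10.0
# default number of prior draws for the iBIC marginal-likelihood sampler
IBIC_SAMPLES = 2000

PARAM_KINDS = {
    "alpha": "unit",
    "alpha_pos": "unit",
    "alpha_neg": "unit",
    "beta": "pos",
    "beta_win": "pos",
    "beta_loss": "pos",
    "rho": "real",
    "rho_win": "real",
    "rho_loss": "real",
    "kappa": "unit",
}


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One member of the reversal-learning model family.

    Parameters
    ----------
    family
        ``"softmax_beta"`` or ``"reinforcement_rho"``.
    n_lr
        1 for a single learning rate, 2 for separate win/loss rates.
    dual_update
        Whether the unchosen action is counterfactually updated.
    use_kappa
        Whether the counterfactual update carries a free discount weight
        (requires ``dual_update``).
    n_choice_params
        1 for a single beta/rho, 2 for separate win/loss values.
    """

    family: str
    n_lr: int = 1
    dual_update: bool = False
    use_kappa: bool = False
    n_choice_params: int = 1

    def __post_init__(self):
        if self.family not in ("softmax_beta", "reinforcement_rho"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_lr not in (1, 2) or self.n_choice_params not in (1, 2):
            raise ValueError("n_lr and n_choice_params must be 1 or 2")
        if self.use_kappa and not self.dual_update:
            raise ValueError("use_kappa requires dual_update")

    @property
    def param_names(self) -> tuple[str, ...]:
        lr = ("alpha",) if self.n_lr == 1 else ("alpha_pos", "alpha_neg")
        if self.family == "softmax_beta":
            ch = ("beta",) if self.n_choice_params == 1 else ("beta_win", "beta_loss")
        else:
            ch = ("rho",) if self.n_choice_params == 1 else ("rho_win", "rho_loss")
        kap = ("kappa",) if self.use_kappa else ()
        return lr + ch + kap

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def id(self) -> str:
        upd = "DU" if self.dual_update else "SU"
        ch = ("2" if self.n_choice_params == 2 else "1") + (
            "b" if self.family == "softmax_beta" else "rho"
        )
        lr = "2a" if self.n_lr == 2 else "1a"
        return f"{upd}-{ch}{lr}" + ("K" if self.use_kappa else "")


def _spec(family, n_lr, dual, kappa, n_choice):
    return ModelSpec(family, n_lr, dual, kappa, n_choice)


#: the rho-family grid; DU-2rho1a is the winning variant (separate win/loss
#: sensitivities, single learning rate, dual update)
MODEL_GRID_RHO = [
    _spec("reinforcement_rho", nlr, du, ka, nc)
    for nc in (1, 2)
    for nlr in (1, 2)
    for du in (False, True)
    for ka in ((False, True) if du else (False,))
]

MODEL_GRID_BETA = [
    _spec("softmax_beta", nlr, du, ka, nc)
    for nc in (1, 2)
    for nlr in (1, 2)
    for du in (False, True)
    for ka in ((False, True) if du else (False,))
]


# ---------------------------------------------------------------------------
# Parameter transforms (native <-> unconstrained)
# ---------------------------------------------------------------------------

def to_unconstrained(native: np.ndarray, model: ModelSpec) -> np.ndarray:
    """Map native parameters onto the real line (logit / log / identity)."""
    native = np.asarray(native, dtype=float)
    out = np.empty_like(native)
    for i, name in enumerate(model.param_names):
        kind = PARAM_KINDS[name]
        if kind == "unit":
            out[..., i] = special.logit(native[..., i])
        elif kind == "pos":
            out[..., i] = np.log(native[..., i])
        else:
            out[..., i] = native[..., i]
    return out


def to_native(uncon: np.ndarray, model: ModelSpec) -> np.ndarray:
    uncon = np.asarray(uncon, dtype=float)
    out = np.empty_like(uncon)
    for i, name in enumerate(model.param_names):
        kind = PARAM_KINDS[name]
        if kind == "unit":
            out[..., i] = special.expit(uncon[..., i])
        elif kind == "pos":
            out[..., i] = np.exp(uncon[..., i])
        else:
            out[..., i] = uncon[..., i]
    return out


def _model_code(model: ModelSpec) -> tuple[int, int, int, int, int]:
    fam = 0 if model.family == "softmax_beta" else 1
    return (fam, model.n_lr, int(model.dual_update), int(model.use_kappa),
            model.n_choice_params)


def _expand_params(native: np.ndarray, model: ModelSpec) -> np.ndarray:
    """Return (a_pos, a_neg, c_win, c_loss, kappa) from the active subset."""
    native = np.atleast_2d(np.asarray(native, dtype=float))
    names = model.param_names
    d = {n: native[:, i] for i, n in enumerate(names)}
    if model.n_lr == 1:
        a_pos = a_neg = d["alpha"]
    else:
        a_pos, a_neg = d["alpha_pos"], d["alpha_neg"]
    if model.family == "softmax_beta":
        if model.n_choice_params == 1:
            c_win = c_loss = d["beta"]
        else:
            c_win, c_loss = d["beta_win"], d["beta_loss"]
    else:
        if model.n_choice_params == 1:
            c_win = c_loss = d["rho"]
        else:
            c_win, c_loss = d["rho_win"], d["rho_loss"]
    kap = d["kappa"] if model.use_kappa else np.ones_like(a_pos)
    return np.stack([a_pos, a_neg, c_win, c_loss, kap], axis=1)


# ---------------------------------------------------------------------------
# Likelihood core
# ---------------------------------------------------------------------------
# The sequential recursion is compiled with numba when available; a pure
# NumPy fallback keeps the package functional without it.

def _nll_core_py(choices, outcomes, fam, dual, a_pos, a_neg, c_win, c_loss, kap):
    v0 = 0.0
    v1 = 0.0
    nll = 0.0
    prev = 0  # valence of last observed feedback: +1 win, -1 loss, 0 none
    for t in range(choices.shape[0]):
        ch = choices[t]
        if ch < 0:
            continue
        if fam == 0:
            if prev > 0:
                b = c_win
            elif prev < 0:
                b = c_loss
            else:
                b = 0.5 * (c_win + c_loss)
            dv = b * (v1 - v0)
        else:
            dv = v1 - v0
        # log p(chosen) via stable log-sigmoid
        z = dv if ch == 1 else -dv
        if z > 0:
            logp = -np.log1p(np.exp(-z))
        else:
            logp = z - np.log1p(np.exp(z))
        nll -= logp
        lam = outcomes[t]
        if fam == 0:
            lamp = lam
        else:
            lamp = c_win * lam if lam > 0 else c_loss * lam
        a = a_pos if lam > 0 else a_neg
        if ch == 1:
            v1 += a * (lamp - v1)
            if dual:
                v0 += a * (kap * (-lamp) - v0)
        else:
            v0 += a * (lamp - v0)
            if dual:
                v1 += a * (kap * (-lamp) - v1)
        prev = 1 if lam > 0 else -1
    return nll


try:  # pragma: no cover - exercised implicitly when numba is present
    import numba

    _nll_core = numba.njit(cache=True)(_nll_core_py)
except Exception:  # pragma: no cover
    _nll_core = _nll_core_py


def _trial_arrays(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Extract integer choices (A=0, B=1, missing=-1) and ±1 outcomes."""
    t = trials.sort_values("trial")
    ch = t["choice"].to_numpy(dtype=object)
    choices = np.array([0 if c == "A" else 1 if c == "B" else -1 for c in ch],
                       dtype=np.int64)
    out = pd.to_numeric(t["outcome"], errors="coerce").to_numpy(dtype=float)
    out = np.where(choices < 0, 0.0, np.nan_to_num(out))
    return choices, out


def negative_log_likelihood(params, trials, model: ModelSpec) -> float:
    """Negative log likelihood of one subject-session under ``model``.

    ``params`` are native-scale values in ``model.param_names`` order.
    Missing-choice trials contribute nothing and leave the values unchanged.
    """
    params = np.asarray(params, dtype=float)
    if params.shape != (model.n_params,):
        raise ValueError(f"expected {model.n_params} parameters, got {params.shape}")
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite parameter")
    if isinstance(trials, pd.DataFrame):
        choices, outcomes = _trial_arrays(trials)
    else:
        choices, outcomes = trials
    if not np.any(choices >= 0):
        raise ValueError("no valid trials")
    fam, _, dual, _, _ = _model_code(model)
    ex = _expand_params(params, model)[0]
    return float(_nll_core(choices, outcomes, fam, dual,
                           ex[0], ex[1], ex[2], ex[3], ex[4]))


def loglik_batch(params_matrix, trials, model: ModelSpec) -> np.ndarray:
    """Log likelihood for many native parameter vectors at once.

    Vectorised over the rows of ``params_matrix`` (shape ``(M, P)``); the
    trial recursion itself stays sequential. Used by the iBIC sampler.
    """
    if isinstance(trials, pd.DataFrame):
        choices, outcomes = _trial_arrays(trials)
    else:
        choices, outcomes = trials
    fam, _, dual, _, _ = _model_code(model)
    ex = _expand_params(params_matrix, model)
    a_pos, a_neg, c_win, c_loss, kap = (ex[:, i] for i in range(5))
    m = a_pos.shape[0]
    v = np.zeros((m, 2))
    ll = np.zeros(m)
    prev = 0
    mean_c = 0.5 * (c_win + c_loss)
    for t in range(choices.shape[0]):
        ch = choices[t]
        if ch < 0:
            continue
        if fam == 0:
            b = c_win if prev > 0 else (c_loss if prev < 0 else mean_c)
            dv = b * (v[:, 1] - v[:, 0])
        else:
            dv = v[:, 1] - v[:, 0]
        z = dv if ch == 1 else -dv
        ll -= np.logaddexp(0.0, -z)
        lam = outcomes[t]
        lamp = (np.full(m, lam) if fam == 0
                else (c_win * lam if lam > 0 else c_loss * lam))
        a = a_pos if lam > 0 else a_neg
        un = 1 - ch
        v[:, ch] += a * (lamp - v[:, ch])
        if dual:
            v[:, un] += a * (kap * (-lamp) - v[:, un])
        prev = 1 if lam > 0 else -1
    return ll


def value_trajectory(params, trials, model: ModelSpec) -> np.ndarray:
    """Expected values (T+1, 2) before each trial — diagnostic helper."""
    if isinstance(trials, pd.DataFrame):
        choices, outcomes = _trial_arrays(trials)
    else:
        choices, outcomes = trials
    fam, _, dual, _, _ = _model_code(model)
    ex = _expand_params(np.asarray(params, dtype=float), model)[0]
    a_pos, a_neg, c_win, c_loss, kap = ex
    v = np.zeros(2)
    traj = [v.copy()]
    for t in range(len(choices)):
        ch = choices[t]
        if ch >= 0:
            lam = outcomes[t]
            lamp = lam if fam == 0 else (c_win * lam if lam > 0 else c_loss * lam)
            a = a_pos if lam > 0 else a_neg
            v[ch] += a * (lamp - v[ch])
            if dual:
                v[1 - ch] += a * (kap * (-lamp) - v[1 - ch])
        traj.append(v.copy())
    return np.array(traj)


def simulate_choices(params, model: ModelSpec, outcome_if_correct,
                     correct_is_b, rng) -> tuple[np.ndarray, np.ndarray]:
    """Forward-simulate choices from the model on a task schedule.

    Parameters
    ----------
    params
        Native parameters in ``model.param_names`` order.
    outcome_if_correct
        ±1 scheduled outcome for the correct stimulus per trial; the
        incorrect stimulus receives the inverse.
    correct_is_b
        Boolean per trial: True when stimulus B is currently correct.

    Returns
    -------
    choices, outcomes
        Integer choices (A=0/B=1) and the ±1 outcomes received.
    """
    fam, _, dual, _, _ = _model_code(model)
    ex = _expand_params(np.asarray(params, dtype=float), model)[0]
    a_pos, a_neg, c_win, c_loss, kap = ex
    n = len(outcome_if_correct)
    choices = np.empty(n, dtype=np.int64)
    outcomes = np.empty(n, dtype=float)
    v = np.zeros(2)
    prev = 0
    for t in range(n):
        if fam == 0:
            b = c_win if prev > 0 else (c_loss if prev < 0 else 0.5 * (c_win + c_loss))
            dv = b * (v[1] - v[0])
        else:
            dv = v[1] - v[0]
        p_b = special.expit(dv)
        ch = 1 if rng.random() < p_b else 0
        chose_correct = (ch == 1) == bool(correct_is_b[t])
        lam = outcome_if_correct[t] if chose_correct else -outcome_if_correct[t]
        lamp = lam if fam == 0 else (c_win * lam if lam > 0 else c_loss * lam)
        a = a_pos if lam > 0 else a_neg
        v[ch] += a * (lamp - v[ch])
        if dual:
            v[1 - ch] += a * (kap * (-lamp) - v[1 - ch])
        prev = 1 if lam > 0 else -1
        choices[t] = ch
        outcomes[t] = lam
    return choices, outcomes


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class GroupPrior:
    """Multivariate Gaussian over unconstrained parameters."""

    mean: np.ndarray
    cov: np.ndarray
    param_names: tuple[str, ...]

    @property
    def n_hyperparams(self) -> int:
        p = len(self.mean)
        return p + p * (p + 1) // 2


@dataclass
class FitBundle:
    """Per-subject-session estimates for one (model, estimator) pair."""

    model: ModelSpec
    estimator: str
    estimates: pd.DataFrame  # subject_id, session, <native params>, loglik, converged
    prior: GroupPrior | None = None
    ibic: float | None = None
    n_em_iter: int | None = None
    converged: bool = True

    def params_table(self) -> pd.DataFrame:
        """Long table of native parameter values per subject-session."""
        cols = list(self.model.param_names)
        return self.estimates.melt(
            id_vars=["subject_id", "session"], value_vars=cols,
            var_name="measure", value_name="value")


def _iter_sessions(trials: pd.DataFrame):
    for (sid, sess), grp in trials.groupby(["subject_id", "session"], sort=True):
        yield sid, sess, _trial_arrays(grp)


def _minimise(objective, x0s, bound=20.0):
    """Best-of-multistart L-BFGS-B on the unconstrained scale."""
    best = None
    bounds = [(-bound, bound)] * len(x0s[0])
    for x0 in x0s:
        try:
            res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        except Exception:
            continue
        if best is None or res.fun < best.fun:
            best = res
    return best


def _fit_pointwise(trials, model, penalty, multistart, rng, estimator):
    rows = []
    p = model.n_params
    for sid, sess, arrs in _iter_sessions(trials):
        def obj(x):
            nll = negative_log_likelihood(to_native(x, model), arrs, model)
            return nll + penalty(x)

        x0s = [np.zeros(p)] + [rng.normal(0, 1, p) for _ in range(multistart - 1)]
        res = _minimise(obj, x0s)
        if res is None:
            rows.append({"subject_id": sid, "session": sess, "loglik": np.nan,
                         "converged": False,
                         **dict.fromkeys(model.param_names, np.nan)})
            continue
        native = to_native(res.x, model)
        ll = -negative_log_likelihood(native, arrs, model)
        rows.append({"subject_id": sid, "session": sess,
                     **dict(zip(model.param_names, native)),
                     "loglik": ll, "converged": bool(res.success)})
    est = pd.DataFrame(rows)
    return FitBundle(model=model, estimator=estimator, estimates=est)


def fit_ml(trials: pd.DataFrame, model: ModelSpec, multistart: int = 5,
           rng=None) -> FitBundle:
    """Independent maximum-likelihood fit per subject-session."""
    rng = np.random.default_rng(rng)
    return _fit_pointwise(trials, model, lambda x: 0.0, multistart, rng, "ML")


def fit_map0(trials: pd.DataFrame, model: ModelSpec,
             prior_sd: float = MAP0_PRIOR_SD, multistart: int = 5,
             rng=None) -> FitBundle:
    """MAP fit with an uninformative Normal(0, prior_sd) unconstrained prior."""
    rng = np.random.default_rng(rng)
    pen = lambda x: 0.5 * float(np.sum((x / prior_sd) ** 2))
    return _fit_pointwise(trials, model, pen, multistart, rng, "MAP0")


def _hessian_fd(f, x, h=1e-3):
    """Central finite-difference Hessian."""
    p = len(x)
    hess = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p); ei[i] = h
        for j in range(i, p):
            ej = np.zeros(p); ej[j] = h
            if i == j:
                hess[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h ** 2
            else:
                hess[i, j] = hess[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)) / (4 * h ** 2)
    return hess


def _safe_cov(cov: np.ndarray, floor: float = COV_RIDGE) -> np.ndarray:
    """Symmetrise and ridge-repair a covariance to positive definiteness."""
    cov = 0.5 * (cov + cov.T)
    try:
        np.linalg.cholesky(cov)
        return cov
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        w = np.maximum(w, floor)
        warnings.warn("group prior covariance not positive definite; ridge-repaired")
        return v @ np.diag(w) @ v.T


def fit_em(trials: pd.DataFrame, model: ModelSpec, max_iter: int = 40,
           tol: float = 1e-3, rng=None, compute_ibic: bool = True,
           ibic_samples: int = IBIC_SAMPLES) -> FitBundle:
    """Hierarchical fit with an empirical Gaussian group prior (EM).

    The E-step finds each subject-session's MAP estimate under the current
    prior and its Laplace (inverse-Hessian) covariance; the M-step updates
    the prior mean and covariance from the posterior moments. Requires at
    least 10 subject-sessions.
    """
    rng = np.random.default_rng(rng)
    sessions = list(_iter_sessions(trials))
    if len(sessions) < 10:
        raise ValueError("EM requires at least 10 subject-sessions")
    p = model.n_params
    mu = np.zeros(p)
    cov = np.eye(p)
    m_i = np.zeros((len(sessions), p))
    s_i = np.tile(np.eye(p), (len(sessions), 1, 1))
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        cov_inv = np.linalg.inv(cov)
        # E-step: per-session MAP + Laplace curvature under current prior
        for idx, (_, _, arrs) in enumerate(sessions):
            def obj(x):
                d = x - mu
                return (negative_log_likelihood(to_native(x, model), arrs, model)
                        + 0.5 * float(d @ cov_inv @ d))

            x0s = [m_i[idx] if n_iter > 1 else mu.copy()]
            res = _minimise(obj, x0s)
            if res is not None:
                m_i[idx] = res.x
                hess = _hessian_fd(obj, res.x)
                # eigenvalue-floor the curvature so the Laplace covariance
                # is always positive definite
                w, v = np.linalg.eigh(0.5 * (hess + hess.T))
                w = np.maximum(w, 1e-4)
                s_i[idx] = (v / w) @ v.T
        # M-step: full empirical-Bayes moment update
        mu_new = m_i.mean(axis=0)
        dev = m_i - mu_new
        cov_new = (s_i.sum(axis=0) + dev.T @ dev) / len(sessions)
        cov_new = _safe_cov(cov_new + COV_RIDGE * np.eye(p))
        shift = max(np.max(np.abs(mu_new - mu)),
                    np.max(np.abs(cov_new - cov)))
        mu, cov = mu_new, cov_new
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"EM did not converge within {max_iter} iterations")
    rows = []
    for idx, (sid, sess, arrs) in enumerate(sessions):
        native = to_native(m_i[idx], model)
        ll = -negative_log_likelihood(native, arrs, model)
        rows.append({"subject_id": sid, "session": sess,
                     **dict(zip(model.param_names, native)),
                     "loglik": ll, "converged": True})
    prior = GroupPrior(mean=mu, cov=cov, param_names=model.param_names)
    bundle = FitBundle(model=model, estimator="EM",
                       estimates=pd.DataFrame(rows), prior=prior,
                       n_em_iter=n_iter, converged=converged)
    if compute_ibic:
        bundle.ibic = ibic(bundle, trials, n_samples=ibic_samples, rng=rng)
    return bundle


def ibic(bundle: FitBundle, trials: pd.DataFrame,
         n_samples: int = IBIC_SAMPLES, rng=None) -> float:
    """Integrated BIC from a sampled marginal likelihood.

    ``-2 * sum_i log[(1/K) * sum_k p(data_i | theta_k)]`` with ``theta_k``
    drawn from the fitted group prior, plus the number of prior
    hyperparameters times ``log`` of the total valid-trial count.
    """
    if bundle.prior is None:
        raise ValueError("iBIC requires an EM bundle with a group prior")
    if n_samples < 100:
        warnings.warn("iBIC sampler with fewer than 100 draws is unreliable")
    rng = np.random.default_rng(rng)
    model = bundle.model
    draws_u = rng.multivariate_normal(bundle.prior.mean, bundle.prior.cov,
                                      size=n_samples)
    draws = to_native(draws_u, model)
    total_ll = 0.0
    n_valid = 0
    for _, _, arrs in _iter_sessions(trials):
        ll = loglik_batch(draws, arrs, model)
        total_ll += special.logsumexp(ll) - np.log(n_samples)
        n_valid += int(np.sum(arrs[0] >= 0))
    return float(-2.0 * total_ll
                 + bundle.prior.n_hyperparams * np.log(n_valid))


def model_grid(bundles: list[FitBundle]) -> pd.DataFrame:
    """Rank fitted bundles by iBIC; ties broken by fewer parameters."""
    rows = []
    for b in bundles:
        rows.append({"model_id": b.model.id, "family": b.model.family,
                     "n_params": b.model.n_params, "estimator": b.estimator,
                     "ibic": b.ibic})
    tab = pd.DataFrame(rows).sort_values(
        ["ibic", "n_params"], kind="stable").reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    return tab
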