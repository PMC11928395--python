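"""Probabilistic reversal-learning task schedule and synthetic agents.

The task presents two stimuli (A and B); one is "correct" and yields a gain
on 75% of trials, with outcomes pseudorandomised so the assigned
probabilities are exactly true over contiguous blocks of four trials. The
correct stimulus reverses nine times over 150 trials, each reversal spaced
15 ± up to 3 trials apart (uniform over integers). Agents are
reinforcement-learning models (see :mod:`relistab.rl`) with a lognormal
reaction-time model featuring post-loss slowing, an optional lapse
probability producing missing responses, and an additive session-2 drift on
the transformed parameters to emulate between-session performance
improvement.

Data-quality screens mirror common online-study practice: an exact binomial
test against chance performance, and careless/insufficient-effort flags for
runs of missing responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import rl

__all__ = [
    "TaskConfig",
    "TrialSchedule",
    "AgentParams",
    "PopulationSpec",
    "generate_schedule",
    "simulate_agent",
    "simulate_cohort",
    "screen_chance",
    "cie_screen",
    "read_trials",
    "write_trials",
]

TRIAL_COLUMNS = ["subject_id", "session", "trial", "correct_stimulus",
                 "choice", "chose_best", "outcome", "rt_ms", "is_reversal"]


@dataclass(frozen=True)
class TaskConfig:
    """Reversal-learning schedule parameters (defaults match the task design)."""

    n_trials: int = 150
    n_reversals: int = 9
    base_interval: int = 15
    interval_jitter: int = 3
    p_reward_correct: float = 0.75
    block_len: int = 4
    response_window: float = 2000.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_trials < self.n_reversals * (self.base_interval - self.interval_jitter):
            raise ValueError("reversals cannot fit within n_trials")
        if not 0.5 < self.p_reward_correct <= 1.0:
            raise ValueError("p_reward_correct must be in (0.5, 1]")
        n_gain = self.p_reward_correct * self.block_len
        if abs(n_gain - round(n_gain)) > 1e-9:
            raise ValueError(
                "p_reward_correct * block_len must be an integer "
                "(pseudorandomisation requirement)")


@dataclass
class TrialSchedule:
    """Per-trial ground truth of one simulated task run."""

    config: TaskConfig
    correct_stimulus: np.ndarray   # 'A' / 'B' per trial
    outcome_if_correct: np.ndarray   # +1 / -1
    outcome_if_incorrect: np.ndarray
    is_reversal_trial: np.ndarray   # bool; True where correct stimulus flips

    def __len__(self) -> int:
        return len(self.correct_stimulus)


def generate_schedule(config: TaskConfig, rng=None) -> TrialSchedule:
    """Draw a task schedule: reversal positions, stimulus roles, outcomes.

    Inter-reversal gaps are uniform on integers
    ``[base_interval - jitter, base_interval + jitter]``; the gap sequence is
    redrawn until all reversals fit inside ``n_trials``. Outcome
    pseudorandomisation blocks are aligned to absolute trial index; the final
    partial block samples from a shuffled full-block pattern truncated to its
    length.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    lo = config.base_interval - config.interval_jitter
    hi = config.base_interval + config.interval_jitter
    n = config.n_trials

    if config.n_reversals > 0:
        for _ in range(10_000):
            gaps = rng.integers(lo, hi + 1, size=config.n_reversals)
            positions = np.cumsum(gaps)  # 0-based index of each reversal trial
            if positions[-1] < n:
                break
        else:  # pragma: no cover - unreachable for feasible configs
            raise ValueError("could not place reversals within n_trials")
    else:
        positions = np.array([], dtype=int)

    is_rev = np.zeros(n, dtype=bool)
    is_rev[positions] = True
    first = rng.choice(["A", "B"])
    flips = np.cumsum(is_rev) % 2
    correct = np.where(flips == 0, first, "B" if first == "A" else "A")

    n_gain = round(config.p_reward_correct * config.block_len)
    pattern = np.array([1] * n_gain + [-1] * (config.block_len - n_gain))
    out_correct = np.empty(n, dtype=int)
    for start in range(0, n, config.block_len):
        blk = rng.permutation(pattern)
        stop = min(start + config.block_len, n)
        out_correct[start:stop] = blk[: stop - start]
    return TrialSchedule(
        config=config,
        correct_stimulus=correct,
        outcome_if_correct=out_correct,
        outcome_if_incorrect=-out_correct,
        is_reversal_trial=is_rev,
    )


@dataclass
class AgentParams:
    """Generative parameters of one simulated subject.

    Only the fields required by ``model_id`` need to be set; the reaction
    time model is lognormal (``rt_mu``, ``rt_sigma`` on the log-ms scale)
    with an additive post-loss slowing of ``rt_loss_shift`` ms, truncated at
    the response window. ``session2_gain`` is added to every transformed
    model parameter when simulating session 2, emulating practice-driven
    improvement. ``lapse_p`` is the per-trial probability of a missing
    response.
    """

    model_id: str = "DU-2rho1a"
    alpha: float = np.nan
    alpha_pos: float = np.nan
    alpha_neg: float = np.nan
    beta: float = np.nan
    beta_win: float = np.nan
    beta_loss: float = np.nan
    rho: float = np.nan
    rho_win: float = np.nan
    rho_loss: float = np.nan
    kappa: float = np.nan
    rt_mu: float = 6.2
    rt_sigma: float = 0.25
    rt_loss_shift: float = 40.0
    session2_gain: float = 0.0
    lapse_p: float = 0.0

    def model_spec(self) -> rl.ModelSpec:
        return model_from_id(self.model_id)

    def native_vector(self, session: int = 1) -> np.ndarray:
        spec = self.model_spec()
        vals = np.array([getattr(self, name) for name in spec.param_names])
        if np.any(np.isnan(vals)):
            missing = [n for n, v in zip(spec.param_names, vals) if np.isnan(v)]
            raise ValueError(f"model {self.model_id} requires {missing}")
        if session == 2 and self.session2_gain != 0.0:
            u = rl.to_unconstrained(vals, spec) + self.session2_gain
            vals = rl.to_native(u, spec)
        return vals


_MODEL_IDS = {m.id: m for m in rl.MODEL_GRID_RHO + rl.MODEL_GRID_BETA}


def model_from_id(model_id: str) -> rl.ModelSpec:
    try:
        return _MODEL_IDS[model_id]
    except KeyError:
        raise ValueError(f"unknown model_id {model_id!r}") from None


def simulate_agent(params: AgentParams, schedule: TrialSchedule,
                   session: int, rng, subject_id: str = "sim") -> pd.DataFrame:
    """Simulate one subject-session on a schedule; returns a trial table."""
    rng = np.random.default_rng(rng)
    spec = params.model_spec()
    native = params.native_vector(session)
    correct_is_b = schedule.correct_stimulus == "B"
    choices, outcomes = rl.simulate_choices(
        native, spec, schedule.outcome_if_correct, correct_is_b, rng)

    n = len(schedule)
    window = schedule.config.response_window
    rts = np.minimum(rng.lognormal(params.rt_mu, params.rt_sigma, size=n), window)
    # post-loss slowing: shift trials preceded by a loss
    prev_loss = np.zeros(n, dtype=bool)
    prev_loss[1:] = outcomes[:-1] < 0
    rts = np.minimum(rts + params.rt_loss_shift * prev_loss, window)

    lapse = rng.random(n) < params.lapse_p
    choice_lbl = np.where(choices == 1, "B", "A").astype(object)
    chose_best = (choice_lbl == schedule.correct_stimulus)
    out = outcomes.astype(object)
    rt_col = rts.astype(object)
    choice_lbl[lapse] = None
    out[lapse] = None
    rt_col[lapse] = None
    chose_best = np.where(lapse, None, chose_best)
    return pd.DataFrame({
        "subject_id": subject_id,
        "session": session,
        "trial": np.arange(1, n + 1),
        "correct_stimulus": schedule.correct_stimulus,
        "choice": choice_lbl,
        "chose_best": chose_best,
        "outcome": out,
        "rt_ms": rt_col,
        "is_reversal": schedule.is_reversal_trial,
    })


@dataclass
class PopulationSpec:
    """Between-subject distribution of agent parameters.

    ``param_dists`` maps model parameter names to ``(mean, sd)`` Gaussians on
    the *unconstrained* scale (logit for learning rates and kappa, log for
    inverse temperatures, identity for reinforcement sensitivities), which
    keeps sampled natives inside their ranges. RT parameters are Gaussian on
    their own scales. The defaults describe a moderately heterogeneous
    cohort of the winning dual-update model with aversive losses
    (``rho_loss`` > 0 so that lose-shift exceeds win-shift) and mild
    session-2 improvement.
    """

    model_id: str = "DU-2rho1a"
    param_dists: dict = field(default_factory=lambda: {
        "alpha": (0.9, 0.5),          # logit scale -> mean alpha ~ 0.71
        "rho_win": (2.0, 0.6),        # identity scale
        "rho_loss": (0.9, 0.35),
    })
    rt_mu: tuple[float, float] = (6.2, 0.15)
    rt_sigma: tuple[float, float] = (0.25, 0.05)
    rt_loss_shift: tuple[float, float] = (40.0, 15.0)
    session2_gain: float = 0.1
    lapse_p: float = 0.0

    def sample(self, n_subjects: int, rng) -> list[AgentParams]:
        rng = np.random.default_rng(rng)
        spec = model_from_id(self.model_id)
        agents = []
        for _ in range(n_subjects):
            uncon = np.array([rng.normal(*self.param_dists[name])
                              for name in spec.param_names])
            native = rl.to_native(uncon, spec)
            kwargs = dict(zip(spec.param_names, native))
            agents.append(AgentParams(
                model_id=self.model_id,
                rt_mu=rng.normal(*self.rt_mu),
                rt_sigma=abs(rng.normal(*self.rt_sigma)),
                rt_loss_shift=rng.normal(*self.rt_loss_shift),
                session2_gain=self.session2_gain,
                lapse_p=self.lapse_p,
                **kwargs,
            ))
        return agents


def simulate_cohort(pop: PopulationSpec, n_subjects: int,
                    config: TaskConfig | None = None, rng=None,
                    sessions: tuple[int, ...] = (1, 2)) -> pd.DataFrame:
    """Simulate a two-session cohort; each session gets a fresh schedule.

    Subjects keep their generative parameters across sessions (up to the
    session-2 drift), which is what makes their behaviour a stable trait
    that reliability analyses can try to recover.
    """
    rng = np.random.default_rng(rng)
    config = config or TaskConfig()
    agents = pop.sample(n_subjects, rng)
    tables = []
    for i, agent in enumerate(agents):
        sid = f"s{i + 1:04d}"
        for sess in sessions:
            schedule = generate_schedule(config, rng)
            tables.append(simulate_agent(agent, schedule, sess, rng, subject_id=sid))
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# Data-quality screens
# ---------------------------------------------------------------------------

def screen_chance(trials: pd.DataFrame, alpha_level: float = 0.05) -> bool:
    """Exact binomial screen for above-chance performance.

    Returns True (keep) when the count of best-stimulus choices among valid
    trials is significantly *greater* than chance (p = 0.5) at
    ``alpha_level`` under a one-sided exact binomial test; subjects not
    demonstrably above chance are excluded (False).
    """
    valid = trials["choice"].notna() & (trials["choice"] != "")
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no valid trials to screen")
    n_best = int(trials.loc[valid, "chose_best"].astype(bool).sum())
    p = stats.binomtest(n_best, n_valid, p=0.5, alternative="greater").pvalue
    return bool(p < alpha_level)


def cie_screen(trials: pd.DataFrame, max_consecutive: int = 5,
               max_missing_frac: float = 0.05) -> dict:
    """Careless/insufficient-effort flags.

    ``terminated_early`` is set when ``max_consecutive`` or more missing
    choices occur in a row (the live task aborts at that point);
    ``excess_missing`` when missing choices exceed ``max_missing_frac`` of
    all trials.
    """
    missing = (trials["choice"].isna() | (trials["choice"] == "")).to_numpy()
    run = best = 0
    for m in missing:
        run = run + 1 if m else 0
        best = max(best, run)
    return {
        "terminated_early": bool(best >= max_consecutive),
        "excess_missing": bool(missing.mean() > max_missing_frac),
    }


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table CSV (missing values as empty fields)."""
    trials.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table CSV written by :func:`write_trials`."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    df["choice"] = df["choice"].where(df["choice"].notna(), None)
    df["outcome"] = pd.to_numeric(df["outcome"], errors="coerce")
    df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
    df["chose_best"] = df["chose_best"].map(
        {True: True, False: False, "True": True, "False": False})
    df["is_reversal"] = df["is_reversal"].astype(bool)
    return df
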