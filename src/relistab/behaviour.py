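"""Behavioural measures of reversal-learning performance.

Nine measures are derived from trial-level choices: accuracy (probability
of choosing the currently best stimulus), perseveration (probability of
choosing the now-worst stimulus after having collected two losses from it
since the last reversal), stay probabilities (overall and split by
previous-trial win/loss) and reaction times (overall, split by previous
feedback, and the win-loss difference).

Each measure can be estimated three ways per subject and session:
``mean`` uses raw per-subject-session proportions or means; ``separate``
fits one mixed-effects model per session (logistic for binary measures,
linear for RTs) with a subject random intercept; ``joint`` fits a single
model over both sessions with a session fixed effect plus a subject random
intercept and random session slope. Model-based subject values are the
inverse-link transform of the subject-specific (shrunken) linear
predictor.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "MEASURES",
    "PROPORTION_MEASURES",
    "RT_MEASURES",
    "trial_indicators",
    "estimate_measures",
    "feedback_effect_tests",
    "mean_measure",
]

PROPORTION_MEASURES = ("accuracy", "perseveration", "stay", "stay_win", "stay_loss")
RT_MEASURES = ("rt", "rt_win", "rt_loss", "rt_win_minus_loss")
MEASURES = PROPORTION_MEASURES + RT_MEASURES
METHODS = ("mean", "separate", "joint")


def trial_indicators(trials: pd.DataFrame) -> pd.DataFrame:
    """Augment a trial table with per-trial behavioural indicator columns.

    Adds ``valid``, ``chose_best``, ``stayed`` (same choice as the
    immediately preceding trial; defined only when both members of the pair
    are valid), ``prev_feedback`` ('win'/'loss' from the preceding valid
    trial outcome), and the perseveration flags ``persev_eligible`` /
    ``persev_choice``: after each reversal, once two losses have been
    incurred from choosing the now-worst stimulus (not necessarily
    consecutively), subsequent trials up to the next reversal are eligible,
    and a worst-stimulus choice on an eligible trial counts as
    perseverative.
    """
    out = []
    for (_, _), grp in trials.groupby(["subject_id", "session"], sort=False):
        g = grp.sort_values("trial").copy()
        choice = g["choice"].to_numpy(dtype=object)
        valid = np.array([c in ("A", "B") for c in choice])
        correct = g["correct_stimulus"].to_numpy(dtype=object)
        outcome = pd.to_numeric(g["outcome"], errors="coerce").to_numpy()
        is_rev = g["is_reversal"].to_numpy(dtype=bool)
        n = len(g)

        chose_best = np.full(n, np.nan, dtype=object)
        chose_best[valid] = (choice[valid] == correct[valid])

        stayed = np.full(n, np.nan, dtype=object)
        prev_fb = np.full(n, None, dtype=object)
        for t in range(1, n):
            if valid[t] and valid[t - 1]:
                stayed[t] = choice[t] == choice[t - 1]
                prev_fb[t] = "win" if outcome[t - 1] > 0 else "loss"

        persev_eligible = np.zeros(n, dtype=bool)
        persev_choice = np.full(n, np.nan, dtype=object)
        in_post_reversal = False
        losses_from_worst = 0
        for t in range(n):
            if is_rev[t]:
                in_post_reversal = True
                losses_from_worst = 0
            worst = "A" if correct[t] == "B" else "B"
            if in_post_reversal and losses_from_worst >= 2:
                persev_eligible[t] = True
                if valid[t]:
                    persev_choice[t] = choice[t] == worst
            if in_post_reversal and valid[t] and choice[t] == worst and outcome[t] < 0:
                losses_from_worst += 1
        g["valid"] = valid
        g["chose_best"] = chose_best
        g["stayed"] = stayed
        g["prev_feedback"] = prev_fb
        g["persev_eligible"] = persev_eligible
        g["persev_choice"] = persev_choice
        out.append(g)
    return pd.concat(out, ignore_index=True)


def _measure_frame(ind: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Trial-level response frame (subject_id, session, y) for one measure."""
    rt = pd.to_numeric(ind["rt_ms"], errors="coerce")
    if measure == "accuracy":
        m = ind["valid"]
        y = ind["chose_best"]
    elif measure == "perseveration":
        m = ind["persev_eligible"] & ind["valid"]
        y = ind["persev_choice"]
    elif measure == "stay":
        m = ind["stayed"].notna()
        y = ind["stayed"]
    elif measure in ("stay_win", "stay_loss"):
        fb = "win" if measure.endswith("win") else "loss"
        m = ind["stayed"].notna() & (ind["prev_feedback"] == fb)
        y = ind["stayed"]
    elif measure == "rt":
        m = ind["valid"] & rt.notna()
        y = rt
    elif measure in ("rt_win", "rt_loss"):
        fb = "win" if measure.endswith("win") else "loss"
        m = ind["valid"] & rt.notna() & (ind["prev_feedback"] == fb)
        y = rt
    else:
        raise ValueError(f"unknown measure {measure!r}")
    df = ind.loc[m, ["subject_id", "session"]].copy()
    df["y"] = pd.to_numeric(y[m], errors="coerce").astype(float)
    return df.dropna(subset=["y"])


def mean_measure(ind: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Raw per-subject-session value of one measure (the 'mean' method)."""
    if measure == "rt_win_minus_loss":
        win = mean_measure(ind, "rt_win").set_index(["subject_id", "session"])
        loss = mean_measure(ind, "rt_loss").set_index(["subject_id", "session"])
        out = (win["value"] - loss["value"]).rename("value").reset_index()
        return out
    df = _measure_frame(ind, measure)
    return (df.groupby(["subject_id", "session"])["y"].mean()
            .rename("value").reset_index())


def _binary_mixed(df: pd.DataFrame, joint: bool) -> pd.DataFrame:
    """Mixed-effects logistic fit; subject values from VB posterior means."""
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    df = df.copy()
    df["session_c"] = df["session"] - df["session"].mean()
    if joint:
        formula = "y ~ session_c"
        vc = {"subj": "0 + C(subject_id)", "slope": "0 + C(subject_id):session_c"}
    else:
        formula = "y ~ 1"
        vc = {"subj": "0 + C(subject_id)"}
    model = BinomialBayesMixedGLM.from_formula(formula, vc, df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit_vb()
    fe = dict(zip(model.exog_names, res.fe_mean))
    re_mean = dict(zip(model.vc_names, res.vc_mean))

    rows = []
    for (sid, sess), _ in df.groupby(["subject_id", "session"]):
        s_c = sess - df["session"].mean() if joint else 0.0
        lin = fe.get("Intercept", 0.0) + fe.get("session_c", 0.0) * s_c
        lin += re_mean.get(f"C(subject_id)[{sid}]", 0.0)
        if joint:
            lin += re_mean.get(f"C(subject_id)[{sid}]:session_c", 0.0) * s_c
        rows.append({"subject_id": sid, "session": sess,
                     "value": float(special.expit(lin))})
    return pd.DataFrame(rows)


def _linear_mixed(df: pd.DataFrame, joint: bool) -> pd.DataFrame:
    """Mixed-effects linear fit; subject values from conditional modes."""
    import statsmodels.formula.api as smf

    df = df.copy()
    df["session_c"] = df["session"] - df["session"].mean()
    formula = "y ~ session_c" if joint else "y ~ 1"
    re_formula = "~session_c" if joint else "~1"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["subject_id"],
                            re_formula=re_formula)
        res = model.fit(method="lbfgs", maxiter=200)
    fe = res.fe_params
    rand = res.random_effects
    rows = []
    for (sid, sess), _ in df.groupby(["subject_id", "session"]):
        s_c = sess - df["session"].mean() if joint else 0.0
        lin = fe.get("Intercept", 0.0) + fe.get("session_c", 0.0) * s_c
        re = rand[sid]
        lin += re.get("Group", re.iloc[0])
        if joint and "session_c" in re:
            lin += re["session_c"] * s_c
        rows.append({"subject_id": sid, "session": sess, "value": float(lin)})
    return pd.DataFrame(rows)


def _model_measure(ind: pd.DataFrame, measure: str, method: str) -> pd.DataFrame:
    if measure == "rt_win_minus_loss":
        win = _model_measure(ind, "rt_win", method).set_index(["subject_id", "session"])
        loss = _model_measure(ind, "rt_loss", method).set_index(["subject_id", "session"])
        return (win["value"] - loss["value"]).rename("value").reset_index()
    binary = measure in PROPORTION_MEASURES
    joint = method == "joint"
    if joint:
        frames = [_measure_frame(ind, measure)]
    else:
        base = _measure_frame(ind, measure)
        frames = [base[base["session"] == s] for s in sorted(base["session"].unique())]
    fits = []
    for df in frames:
        if df["subject_id"].nunique() < 2:
            raise ValueError("mixed-model methods need at least 2 subjects")
        fits.append(_binary_mixed(df, joint) if binary else _linear_mixed(df, joint))
    return pd.concat(fits, ignore_index=True)


def estimate_measures(trials: pd.DataFrame, measures=MEASURES,
                      method: str = "mean") -> pd.DataFrame:
    """Per-subject-session estimates of behavioural measures.

    Returns a long MeasureTable (subject_id, session, measure, method,
    value). Model-based methods that fail to converge fall back to the raw
    means for that measure with a warning.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if isinstance(measures, str):
        measures = [measures]
    ind = trials if "valid" in trials.columns else trial_indicators(trials)
    frames = []
    for measure in measures:
        if measure not in MEASURES:
            raise ValueError(f"unknown measure {measure!r}")
        if method == "mean":
            vals = mean_measure(ind, measure)
        else:
            try:
                vals = _model_measure(ind, measure, method)
            except Exception as exc:  # non-convergence / degenerate data
                warnings.warn(
                    f"{method} estimation failed for {measure} ({exc}); "
                    "falling back to raw means")
                vals = mean_measure(ind, measure)
        vals = vals.copy()
        vals["measure"] = measure
        vals["method"] = method
        frames.append(vals)
    out = pd.concat(frames, ignore_index=True)
    return out[["subject_id", "session", "measure", "method", "value"]]


def feedback_effect_tests(trials: pd.DataFrame) -> dict:
    """Previous-feedback effects on staying and reaction time.

    Fits a mixed-effects logistic regression of staying on previous
    feedback (win = 1) with a subject random intercept, and a mixed-effects
    linear regression of RT on previous feedback. Positive stay
    coefficients mean more staying after wins; negative RT coefficients
    mean faster responding after wins.
    """
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
    import statsmodels.formula.api as smf

    ind = trials if "valid" in trials.columns else trial_indicators(trials)
    df = ind[ind["stayed"].notna() & ind["prev_feedback"].notna()].copy()
    if df["prev_feedback"].nunique() < 2:
        raise ValueError("both feedback levels required")
    df["prev_win"] = (df["prev_feedback"] == "win").astype(float)
    df["stay_y"] = pd.to_numeric(df["stayed"], errors="coerce").astype(float)
    model = BinomialBayesMixedGLM.from_formula(
        "stay_y ~ prev_win", {"subj": "0 + C(subject_id)"}, df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit_vb()
    i = model.exog_names.index("prev_win")
    coef, sd = float(res.fe_mean[i]), float(res.fe_sd[i])
    z = coef / sd
    stay = {"coef": coef, "stat": z,
            "p": float(2 * stats.norm.sf(abs(z)))}

    rt_df = ind[ind["valid"] & ind["prev_feedback"].notna()].copy()
    rt_df["rt"] = pd.to_numeric(rt_df["rt_ms"], errors="coerce")
    rt_df = rt_df.dropna(subset=["rt"])
    rt_df["prev_win"] = (rt_df["prev_feedback"] == "win").astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lm = smf.mixedlm("rt ~ prev_win", rt_df,
                         groups=rt_df["subject_id"]).fit(method="lbfgs")
    rt = {"coef": float(lm.fe_params["prev_win"]),
          "stat": float(lm.tvalues["prev_win"]),
          "p": float(lm.pvalues["prev_win"])}
    return {"stay": stay, "rt": rt}
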