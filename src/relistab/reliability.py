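"""Test-retest reliability: variance decomposition, ICC(A,1), split-half.

A subject × session measure table is decomposed with a two-way ANOVA into a
between-subject mean square (MSr), a within-subject session mean square
(MSc) and an error mean square (MSe):

    Between = k/(n-1) * sum_i (xbar_i - xbar)^2
    Within  = n/(k-1) * sum_j (xbar_j - xbar)^2
    Error   = (SS - (n-1)*Between - (k-1)*Within) / ((n-1)(k-1))

The within-subject component is corrected by k/n before the three
components are normalised to proportions that sum to one — the quantities
whose sampling stability the :mod:`relistab.stability` module tracks. The
intraclass correlation for absolute agreement of single measurements is

    ICC(A,1) = (MSr - MSe) / (MSr + (k-1)*MSe + (k/n)*(MSc - MSe))

interpreted on the conventional scale poor (< 0.4), fair, good,
excellent (>= 0.75).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarComponents",
    "ICCResult",
    "variance_components",
    "icc_a1",
    "icc_label",
    "split_half",
    "between_session_correlations",
]


@dataclass
class VarComponents:
    between: float          # MSr
    within: float           # MSc
    error: float            # MSe
    within_corrected: float  # MSc * k / n
    proportions: tuple[float, float, float]  # (between, within_corrected, error)
    n: int
    k: int


@dataclass
class ICCResult:
    icc_a1: float
    ci_low: float | None
    ci_high: float | None
    label: str


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("expected an n x 2 subject-by-session matrix")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in measure matrix")
    return X


def variance_components(X) -> VarComponents:
    """Two-way ANOVA mean squares and normalised variance proportions."""
    X = _as_matrix(X)
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    between = k / (n - 1) * np.sum((row_means - grand) ** 2)
    within = n / (k - 1) * np.sum((col_means - grand) ** 2)
    ss = np.sum((X - grand) ** 2)
    if ss <= 0:
        raise ValueError("degenerate table: zero total variance")
    error = (ss - (n - 1) * between - (k - 1) * within) / ((n - 1) * (k - 1))
    if error < 0:
        # numerically possible at rounding level only; the decomposition is exact
        warnings.warn("negative error mean square floored at 0")
        error = 0.0
    within_corrected = within * k / n
    total = between + within_corrected + error
    props = (between / total, within_corrected / total, error / total)
    return VarComponents(between=float(between), within=float(within),
                         error=float(error),
                         within_corrected=float(within_corrected),
                         proportions=tuple(float(p) for p in props),
                         n=n, k=k)


def icc_label(icc: float) -> str:
    if icc < 0.4:
        return "poor"
    if icc < 0.6:
        return "fair"
    if icc < 0.75:
        return "good"
    return "excellent"


def icc_a1(X, ci: bool = True, alpha: float = 0.05) -> ICCResult:
    """ICC for two-way absolute agreement of single measurements.

    The confidence interval uses the standard F-distribution approximation
    with Satterthwaite degrees of freedom.
    """
    vc = variance_components(X)
    n, k = vc.n, vc.k
    msr, msc, mse = vc.between, vc.within, vc.error
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom
    lo = hi = None
    if ci:
        a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
        b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
        if np.isfinite(a) and (a * msc + b * mse) > 0:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1)
                + (b * mse) ** 2 / ((n - 1) * (k - 1)))
            f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr)
            lo, hi = float(lo), float(hi)
        else:
            lo, hi = float(icc), float(icc)
    return ICCResult(icc_a1=float(icc), ci_low=lo, ci_high=hi,
                     label=icc_label(float(icc)))


def split_half(trials: pd.DataFrame, measure_fn, n_splits: int = 100,
               rng=None) -> float:
    """Permutation split-half reliability with Spearman-Brown correction.

    For each split, every subject's eligible trials are randomly divided
    into two halves, ``measure_fn(half)`` is evaluated per half, and the
    Pearson correlation of the half scores across subjects is
    Spearman-Brown corrected (2r / (1 + r)); the corrected values are
    averaged over ``n_splits`` random splits.

    ``measure_fn`` maps a per-subject trial table to a scalar.
    """
    rng = np.random.default_rng(rng)
    groups = {sid: g.reset_index(drop=True)
              for sid, g in trials.groupby("subject_id")}
    if any(len(g) < 2 for g in groups.values()):
        raise ValueError("every subject needs at least 2 eligible trials")
    estimates = []
    for _ in range(n_splits):
        h1, h2 = [], []
        for g in groups.values():
            idx = rng.permutation(len(g))
            half = len(g) // 2
            h1.append(measure_fn(g.iloc[idx[:half]]))
            h2.append(measure_fn(g.iloc[idx[half:]]))
        h1, h2 = np.asarray(h1), np.asarray(h2)
        if np.std(h1) == 0 or np.std(h2) == 0:
            continue
        r = stats.pearsonr(h1, h2).statistic
        estimates.append(2 * r / (1 + r))
    if not estimates:
        raise ValueError("all splits degenerate")
    return float(np.mean(estimates))


def between_session_correlations(measures: pd.DataFrame) -> dict:
    """Session-1 vs session-2 Pearson and Spearman correlations.

    ``measures`` is long format with columns subject_id, session, value
    (one measure at a time), or an n x 2 matrix.
    """
    if isinstance(measures, pd.DataFrame) and "session" in measures.columns:
        wide = measures.pivot(index="subject_id", columns="session",
                              values="value").dropna()
        X = wide.to_numpy(dtype=float)
    else:
        X = _as_matrix(measures)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 subjects for correlations")
    out = {"n": int(X.shape[0]), "degenerate": False}
    if np.std(X[:, 0]) == 0 or np.std(X[:, 1]) == 0:
        out.update(pearson_r=np.nan, pearson_p=np.nan,
                   spearman_rho=np.nan, spearman_p=np.nan, degenerate=True)
        return out
    pr = stats.pearsonr(X[:, 0], X[:, 1])
    sr = stats.spearmanr(X[:, 0], X[:, 1])
    out.update(pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
               spearman_rho=float(sr.statistic), spearman_p=float(sr.pvalue))
    return out
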