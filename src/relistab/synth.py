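"""Regression-based generation of statistically related two-session data.

The generator captures a measure's two-session structure in three pieces:
(1) an OLS regression of session-2 values on session-1 values
(``X2 = b0 + b1*X1 + e``), (2) the marginal distribution of the session-1
values, and (3) the distribution of the regression residuals. Both
distributions are chosen from a configurable list of scipy.stats continuous
families by minimising the sum of squared errors between the fitted density
and a histogram density built with Freedman-Diaconis bins. Synthetic
datasets then draw ``X1_synth`` and ``e_synth`` from the fitted
distributions and set ``X2_synth = b0 + b1*X1_synth + e_synth``; synthetic
values are deliberately not clipped to the source measure's range.

A Gaussian noise-injection variant z-scores each session, adds
Normal(0, noise_sd) draws to the session-2 z-scores, and reverses the
z-scoring with each session's original moments, degrading between-session
agreement in a controlled, scale-free way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionFit",
    "FittedDistribution",
    "SynthSpec",
    "CANDIDATES_FAST",
    "CANDIDATES_FULL",
    "fit_session_regression",
    "freedman_diaconis_bins",
    "fit_best_distribution",
    "build_synth_spec",
    "generate_dataset",
    "add_session_noise",
    "generate_ensemble",
]

#: fast, well-behaved candidate families — the package default
CANDIDATES_FAST = (
    "norm", "lognorm", "gamma", "beta", "uniform", "expon", "t",
    "laplace", "logistic", "cauchy", "chi2", "weibull_min", "gumbel_r",
    "rayleigh", "skewnorm",
)

#: broad library of scipy continuous families; excludes families whose MLE
#: is pathologically slow or unstable on small samples
CANDIDATES_FULL = CANDIDATES_FAST + (
    "alpha", "anglit", "arcsine", "argus", "bradford", "burr", "burr12",
    "chi", "cosine", "crystalball", "dgamma", "dweibull", "exponnorm",
    "exponweib", "exponpow", "f", "fatiguelife", "fisk", "foldcauchy",
    "foldnorm", "genlogistic", "gennorm", "genpareto", "genexpon",
    "genextreme", "gengamma", "genhalflogistic", "gibrat", "gompertz",
    "gumbel_l", "halfcauchy", "halflogistic", "halfnorm", "halfgennorm",
    "hypsecant", "invgamma", "invgauss", "invweibull", "johnsonsb",
    "johnsonsu", "kappa3", "laplace_asymmetric", "levy", "levy_l",
    "loggamma", "loglaplace", "lomax", "maxwell", "mielke", "moyal",
    "nakagami", "pareto", "pearson3", "powerlaw", "powernorm",
    "rice", "semicircular", "triang", "truncexpon", "wald",
    "weibull_max", "wrapcauchy",
)


@dataclass
class RegressionFit:
    """OLS fit of session-2 values on session-1 values."""

    beta0: float
    beta1: float
    residuals: np.ndarray


@dataclass
class FittedDistribution:
    """A scipy.stats family selected by histogram-SSE."""

    family: str
    params: tuple
    sse: float
    n_bins: int

    def frozen(self):
        return getattr(stats, self.family)(*self.params)

    def rvs(self, size: int, rng) -> np.ndarray:
        return self.frozen().rvs(size=size, random_state=rng)

    @property
    def mean(self) -> float:
        return float(self.frozen().mean())


@dataclass
class SynthSpec:
    """Everything needed to generate a synthetic two-session ensemble."""

    measure: str
    regression: RegressionFit
    dist_x1: FittedDistribution
    dist_resid: FittedDistribution
    n_datasets: int = 1000
    n: int = 300
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def fit_session_regression(x1, x2) -> RegressionFit:
    """Ordinary least squares of session 2 on session 1, with residuals."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("x1 and x2 must be equal-length 1-d arrays")
    if len(x1) < 3:
        raise ValueError("need at least 3 subjects")
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
        raise ValueError("non-finite values")
    if np.ptp(x1) == 0:
        raise ValueError("constant session-1 values: regression undefined")
    res = stats.linregress(x1, x2)
    fitted = res.intercept + res.slope * x1
    return RegressionFit(beta0=float(res.intercept), beta1=float(res.slope),
                         residuals=x2 - fitted)


def freedman_diaconis_bins(samples: np.ndarray) -> np.ndarray:
    """Freedman-Diaconis histogram bin edges (bin width 2*IQR/n^(1/3))."""
    samples = np.asarray(samples, dtype=float)
    edges = np.histogram_bin_edges(samples, bins="fd")
    if len(edges) < 3:
        edges = np.histogram_bin_edges(samples, bins=10)
    return edges


def fit_best_distribution(samples, candidates=None) -> FittedDistribution:
    """Select the scipy family whose fitted density best matches the data.

    Each candidate family is fitted by its scipy MLE, its density is
    evaluated at the Freedman-Diaconis histogram bin centres, and the
    family with the smallest sum of squared errors against the empirical
    bin densities wins. Families whose fit fails are skipped.
    """
    samples = np.asarray(samples, dtype=float)
    samples = samples[np.isfinite(samples)]
    if len(samples) < 20:
        raise ValueError("need at least 20 samples to fit a distribution")
    if np.ptp(samples) == 0:
        raise ValueError("degenerate sample: zero spread")
    candidates = CANDIDATES_FAST if candidates is None else candidates
    edges = freedman_diaconis_bins(samples)
    density, _ = np.histogram(samples, bins=edges, density=True)
    centres = 0.5 * (edges[:-1] + edges[1:])
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in candidates:
            dist = getattr(stats, name, None)
            if dist is None:
                continue
            try:
                params = dist.fit(samples)
                pdf = dist.pdf(centres, *params)
                if not np.all(np.isfinite(pdf)):
                    continue
                sse = float(np.sum((pdf - density) ** 2))
            except Exception:
                continue
            if best is None or sse < best.sse:
                best = FittedDistribution(family=name, params=tuple(params),
                                          sse=sse, n_bins=len(centres))
    if best is None:
        raise ValueError("no candidate distribution could be fitted")
    return best


def build_synth_spec(x1, x2, measure: str = "measure", candidates=None,
                     **spec_kwargs) -> SynthSpec:
    """Fit regression + distributions on source data and assemble a spec."""
    reg = fit_session_regression(x1, x2)
    return SynthSpec(
        measure=measure,
        regression=reg,
        dist_x1=fit_best_distribution(x1, candidates),
        dist_resid=fit_best_distribution(reg.residuals, candidates),
        **spec_kwargs,
    )


def generate_dataset(spec: SynthSpec, rng) -> pd.DataFrame:
    """Draw one synthetic two-session dataset of ``spec.n`` subjects."""
    rng = np.random.default_rng(rng)
    x1 = spec.dist_x1.rvs(spec.n, rng)
    e = spec.dist_resid.rvs(spec.n, rng)
    x2 = spec.regression.beta0 + spec.regression.beta1 * x1 + e
    if spec.noise_sd > 0:
        x1, x2 = add_session_noise(x1, x2, spec.noise_sd, rng)
    return pd.DataFrame({"session1": x1, "session2": x2})


def add_session_noise(x1, x2, noise_sd: float, rng):
    """Inject scale-free Gaussian noise into session 2.

    Both sessions are z-scored, Normal(0, noise_sd) draws are added to the
    session-2 z-scores, and both sessions are reverse z-scored with their
    own original mean/SD; session 1 is returned unchanged in value.
    """
    rng = np.random.default_rng(rng)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    s1, s2 = np.std(x1, ddof=1), np.std(x2, ddof=1)
    if s1 == 0 or s2 == 0:
        raise ValueError("zero-variance session: cannot z-score")
    if noise_sd == 0:
        return x1.copy(), x2.copy()
    m2 = np.mean(x2)
    z2 = (x2 - m2) / s2 + rng.normal(0.0, noise_sd, size=len(x2))
    return x1.copy(), z2 * s2 + m2


def generate_ensemble(spec: SynthSpec, rng=None) -> pd.DataFrame:
    """Generate ``spec.n_datasets`` independent datasets as one long table.

    One master seed spawns per-dataset child seeds deterministically; the
    returned frame has columns dataset_id, subject, session1, session2 plus
    noise_sd metadata.
    """
    seed = spec.seed if rng is None else rng
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    children = ss.spawn(spec.n_datasets)
    frames = []
    for d, child in enumerate(children):
        df = generate_dataset(spec, np.random.default_rng(child))
        df.insert(0, "subject", np.arange(1, spec.n + 1))
        df.insert(0, "dataset_id", d)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["noise_sd"] = spec.noise_sd
    out["measure"] = spec.measure
    return out
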