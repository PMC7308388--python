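"""Choice-model fitting and discrimination-vector geometry.

The choice model is a probit GLM on the log2 ratios of the three
orthogonal stimulus dimensions, compressed toward chance by a guessing
rate gamma:

    P(right) = gamma/2 + (1 - gamma) * Phi(b_side + X @ b)

Fitting is by direct maximum likelihood (the lapse term makes this a
non-canonical GLM, so a hand-rolled likelihood is required); with
gamma = 0 it reduces exactly to probit regression, which is used as a
cross-check in the test suite.  The fitted (b_num, b_size, b_spacing)
triple is the discrimination vector whose projections onto and angles
with the feature axes quantify non-numerical biases.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess1

from .errors import (
    FitFailureError,
    InvalidArgumentError,
    UndefinedAcuityError,
)
from .stimulus_space import FEATURE_AXES, FeatureAxis, angle_between, feature_axis
from .trials import ChoiceDataset

logger = logging.getLogger(__name__)

__all__ = [
    "GlmFit",
    "DiscriminationVector",
    "GroupTestResult",
    "filter_outlier_trials",
    "fit_choice_glm",
    "discrimination_vector",
    "project_onto_axes",
    "angles_to_axes",
    "weber_fraction",
    "group_level_stats",
    "GAMMA_GRID",
]

#: Default grid for deviance-minimising gamma estimation.
GAMMA_GRID = tuple(np.round(np.arange(0.0, 0.1005, 0.005), 4))


@dataclass(frozen=True)
class GlmFit:
    beta_side: float
    beta_num: float
    beta_size: float
    beta_spacing: float
    gamma: float
    deviance: float
    adj_r2: float
    se: dict[str, float]
    n_trials: int

    @property
    def betas(self) -> np.ndarray:
        return np.array(
            [self.beta_side, self.beta_num, self.beta_size, self.beta_spacing]
        )


@dataclass(frozen=True)
class DiscriminationVector:
    components: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "components", np.asarray(self.components, dtype=float)
        )
        if self.components.shape != (3,):
            raise InvalidArgumentError("discrimination vector must be 3-D")

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.components))


def _default_ratio_binner(ratio: float) -> float:
    """Difficulty bin label: numerosity ratio (min/max) floored to 0.1 width."""
    return math.floor(ratio * 10.0) / 10.0


def filter_outlier_trials(
    data: ChoiceDataset,
    presentation_ms: float = 250.0,
    ratio_binner: Callable[[float], object] = _default_ratio_binner,
) -> tuple[ChoiceDataset, dict]:
    """Remove outlier trials by response time.

    Trials faster than the stimulus presentation time are removed, as are
    trials slower than mean + 2 SD of equally difficult trials (same
    numerosity-ratio bin).  Datasets without response times are returned
    unchanged with a warning (network-generated choices have no RTs).
    """
    if data.response_time is None:
        logger.warning("no response times present; outlier filter skipped")
        return data, {"removed_fast": 0, "removed_slow": 0, "skipped": True}

    rts = np.asarray(data.response_time, dtype=float)
    keep = rts >= presentation_ms
    n_fast = int((~keep).sum())

    bins = np.array([ratio_binner(t.difficulty_ratio) for t in data.trials])
    slow = np.zeros(len(data), dtype=bool)
    for b in np.unique(bins):
        in_bin = (bins == b) & keep
        if in_bin.sum() < 2:
            continue
        mu, sd = rts[in_bin].mean(), rts[in_bin].std(ddof=1)
        slow |= in_bin & (rts > mu + 2.0 * sd)
    keep &= ~slow

    idx = np.flatnonzero(keep)
    filtered = ChoiceDataset(
        trials=[data.trials[i] for i in idx],
        chosen_side=[data.chosen_side[i] for i in idx],
        response_time=[data.response_time[i] for i in idx],
        observer_id=data.observer_id,
        meta=dict(data.meta),
    )
    report = {
        "removed_fast": n_fast,
        "removed_slow": int(slow.sum()),
        "skipped": False,
    }
    return filtered, report


def _design_matrix(data: ChoiceDataset) -> tuple[np.ndarray, np.ndarray]:
    X = np.array(
        [
            [1.0, math.log2(t.r_num), math.log2(t.r_size), math.log2(t.r_spacing)]
            for t in data.trials
        ]
    )
    y = np.array([1.0 if c == "right" else 0.0 for c in data.chosen_side])
    return X, y


def _nll_and_grad(theta, X, y, gamma):
    eta = X @ theta
    phi = stats.norm.pdf(eta)
    p = gamma / 2.0 + (1.0 - gamma) * stats.norm.cdf(eta)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    nll = -np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p))
    w = (y / p - (1.0 - y) / (1.0 - p)) * (1.0 - gamma) * phi
    grad = -(X.T @ w)
    return nll, grad


def _ml_fit(X, y, gamma, free: np.ndarray) -> tuple[np.ndarray, float]:
    """Maximise the likelihood over the columns flagged in ``free``."""
    Xf = X[:, free]

    def f(th):
        return _nll_and_grad(th, Xf, y, gamma)

    res = optimize.minimize(f, np.zeros(Xf.shape[1]), jac=True, method="BFGS")
    if not np.all(np.isfinite(res.x)):
        raise FitFailureError(f"non-finite coefficients: {res}")
    theta = np.zeros(X.shape[1])
    theta[free] = res.x
    return theta, float(res.fun)


def fit_choice_glm(
    data: ChoiceDataset,
    gamma_mode: float | str = 0.01,
    gamma_grid: Sequence[float] = GAMMA_GRID,
) -> GlmFit:
    """Fit the choice model by maximum likelihood.

    ``gamma_mode`` is either a fixed guessing rate or ``"deviance-grid"``,
    in which case gamma is chosen on ``gamma_grid`` to minimise the model
    deviance.  Standard errors come from the observed information matrix.
    """
    X, y = _design_matrix(data)
    if len(y) < X.shape[1]:
        raise InvalidArgumentError(
            f"{len(y)} trials cannot identify {X.shape[1]} coefficients"
        )
    for j, name in ((1, "numerosity"), (2, "size"), (3, "spacing")):
        if len(np.unique(X[:, j])) < 2 and np.any(X[:, j] != 0.0):
            raise InvalidArgumentError(f"no variation in {name} log-ratio")

    all_free = np.ones(4, dtype=bool)
    if gamma_mode == "deviance-grid":
        fits = []
        for g in gamma_grid:
            theta, nll = _ml_fit(X, y, g, all_free)
            fits.append((2.0 * nll, g, theta, nll))
        deviance, gamma, theta, nll = min(fits, key=lambda t: t[0])
        k = 5  # four betas plus gamma
    else:
        gamma = float(gamma_mode)
        if not 0.0 <= gamma < 1.0:
            raise InvalidArgumentError(f"gamma must be in [0, 1), got {gamma}")
        theta, nll = _ml_fit(X, y, gamma, all_free)
        deviance = 2.0 * nll
        k = 4

    # null model: side bias only, same gamma
    null_free = np.array([True, False, False, False])
    _, nll_null = _ml_fit(X, y, gamma, null_free)
    ll, ll_null = -nll, -nll_null
    adj_r2 = 1.0 - (ll - k) / ll_null if ll_null != 0 else float("nan")

    hess = approx_hess1(theta, lambda th: _nll_and_grad(th, X, y, gamma)[0])
    try:
        cov = np.linalg.inv(hess)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        ses = np.full(4, np.nan)
    names = ("beta_side", "beta_num", "beta_size", "beta_spacing")
    return GlmFit(
        beta_side=float(theta[0]),
        beta_num=float(theta[1]),
        beta_size=float(theta[2]),
        beta_spacing=float(theta[3]),
        gamma=gamma,
        deviance=deviance,
        adj_r2=float(adj_r2),
        se={n: float(s) for n, s in zip(names, ses)},
        n_trials=len(y),
    )


def discrimination_vector(fit: GlmFit) -> DiscriminationVector:
    return DiscriminationVector(
        components=np.array([fit.beta_num, fit.beta_size, fit.beta_spacing])
    )


def _resolve_axes(
    axes: Sequence[FeatureAxis | str] | None,
) -> list[FeatureAxis]:
    if axes is None:
        axes = FEATURE_AXES
    return [a if isinstance(a, FeatureAxis) else feature_axis(a) for a in axes]


def project_onto_axes(
    v: DiscriminationVector, axes: Sequence[FeatureAxis | str] | None = None
) -> dict[str, float]:
    """Signed projection of the discrimination vector on each unit axis."""
    out = {}
    for axis in _resolve_axes(axes):
        if abs(np.linalg.norm(axis.direction) - 1.0) > 1e-9:
            raise InvalidArgumentError(f"axis {axis.name!r} is not unit-norm")
        out[axis.name] = float(np.dot(v.components, axis.direction))
    return out


def angles_to_axes(
    v: DiscriminationVector, axes: Sequence[FeatureAxis | str] | None = None
) -> tuple[dict[str, float], list[str]]:
    """Angle (degrees) between the vector and each axis, plus a ranking.

    Returns ``(angles, ranking)`` where ``ranking`` lists axis names from
    closest to farthest.
    """
    if v.magnitude == 0:
        raise InvalidArgumentError("zero discrimination vector")
    angles = {
        axis.name: angle_between(v.components, axis.direction)
        for axis in _resolve_axes(axes)
    }
    ranking = sorted(angles, key=angles.get)
    return angles, ranking


def weber_fraction(fit: GlmFit) -> float:
    """Internal Weber fraction under the equal-variance log-Gaussian model.

    Convention: ``w = ln 2 / (sqrt(2) * b_num)``, obtained by matching
    ``Phi(b_num * log2 r)`` with ``Phi(ln r / (sqrt(2) w))``.  This is a
    documented convention, not a universal definition.
    """
    if fit.beta_num <= 0:
        raise UndefinedAcuityError(
            f"Weber fraction undefined for beta_num = {fit.beta_num}"
        )
    return math.log(2.0) / (math.sqrt(2.0) * fit.beta_num)


@dataclass(frozen=True)
class GroupTestResult:
    name: str
    kind: str
    test: str
    statistic: float
    p_value: float
    p_adjusted: float
    alpha_adjusted: float
    significant: bool
    n: int


def _choose_test(x: np.ndarray, alpha: float = 0.05) -> str:
    """Shapiro-Wilk normality gate: parametric if not rejected."""
    if len(x) < 3 or np.allclose(x, x[0]):
        return "wilcoxon"
    _, p = stats.shapiro(x)
    return "t" if p > alpha else "wilcoxon"


def group_level_stats(
    samples: Mapping[str, np.ndarray | tuple[np.ndarray, np.ndarray]],
    kind: str = "one-sample",
    alpha: float = 0.05,
    popmean: float = 0.0,
) -> list[GroupTestResult]:
    """Bonferroni-corrected group comparisons.

    ``kind`` selects the family: ``one-sample`` (each value is an array,
    tested against ``popmean``), ``paired`` (each value is an ``(a, b)``
    tuple) or ``unpaired`` (``(a, b)`` tuple, Mann-Whitney U).  Normality
    (Shapiro-Wilk) decides between t and Wilcoxon for the first two.
    """
    if kind not in ("one-sample", "paired", "unpaired"):
        raise InvalidArgumentError(f"unknown kind {kind!r}")
    m = len(samples)
    if m == 0:
        raise InvalidArgumentError("no comparisons supplied")
    alpha_adj = alpha / m
    results = []
    for name, value in samples.items():
        if kind == "one-sample":
            x = np.asarray(value, dtype=float)
            if len(x) < 2:
                raise InvalidArgumentError(f"{name}: need >= 2 observations")
            d = x - popmean
            test = _choose_test(d)
            if test == "t":
                stat, p = stats.ttest_1samp(x, popmean)
            else:
                if np.allclose(d, 0.0):
                    stat, p = 0.0, 1.0
                else:
                    stat, p = stats.wilcoxon(d)
            n = len(x)
        else:
            a, b = (np.asarray(v, dtype=float) for v in value)
            if len(a) < 2 or len(b) < 2:
                raise InvalidArgumentError(f"{name}: need >= 2 observations")
            if kind == "paired":
                d = a - b
                test = _choose_test(d)
                if test == "t":
                    stat, p = stats.ttest_rel(a, b)
                else:
                    if np.allclose(d, 0.0):
                        stat, p = 0.0, 1.0
                    else:
                        stat, p = stats.wilcoxon(a, b)
                n = len(a)
            else:
                test = "mannwhitneyu"
                stat, p = stats.mannwhitneyu(a, b)
                n = len(a) + len(b)
        results.append(
            GroupTestResult(
                name=name,
                kind=kind,
                test=test,
                statistic=float(stat),
                p_value=float(p),
                p_adjusted=float(min(1.0, p * m)),
                alpha_adjusted=alpha_adj,
                significant=bool(p < alpha_adj),
                n=n,
            )
        )
    return results
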