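"""Representational similarity analysis over a 27-condition probe set.

Network RDMs use 1 - Pearson correlation between per-condition mean
top-layer activation patterns; categorical model RDMs use absolute
log2 differences of single feature values.  Relatedness is Kendall's
tau-a (ties count against agreement) with a one-sided signed-rank test
across seed replicates, Benjamini-Hochberg FDR across the candidate
set, and replicate-based noise-ceiling bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InvalidArgumentError
from .stimulus_space import StimulusPoint

__all__ = [
    "Rdm",
    "build_probe_set",
    "mean_activation_patterns",
    "model_rdm",
    "categorical_rdm",
    "rank_transform_rdm",
    "kendall_tau_a",
    "relatedness_test",
    "noise_ceiling",
    "rdm_glm_fit",
]


@dataclass
class Rdm:
    """Symmetric dissimilarity matrix with zero diagonal over labelled conditions."""

    matrix: np.ndarray
    conditions: tuple
    metric: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InvalidArgumentError("RDM must be square")
        if m.shape[0] != len(self.conditions):
            raise InvalidArgumentError("one condition label per row required")
        if not np.allclose(m, m.T, atol=1e-12):
            raise InvalidArgumentError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise InvalidArgumentError("RDM diagonal must be zero")
        self.matrix = m
        self.conditions = tuple(self.conditions)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(self.n, k=-1)
        return self.matrix[i, j]


def build_probe_set(
    num_levels: Sequence[float],
    size_levels: Sequence[float],
    spacing_levels: Sequence[float],
    level_indices: tuple[Sequence[int], Sequence[int], Sequence[int]] = (
        (0, 8, 12),
        (0, 8, 12),
        (0, 8, 12),
    ),
    instances: int = 10,
) -> list[StimulusPoint]:
    """Select probe levels by grid index and replicate each combination.

    Note: with the default 13-level grids the printed middle probe values
    correspond to 0-based grid index 8 (e.g. numerosity 7*4^(8/12) ~ 17.6,
    i.e. 18 dots), not to the geometric midpoint of the range.
    """
    from .stimulus_space import build_full_grid

    selected = []
    for levels, idxs in zip((num_levels, size_levels, spacing_levels), level_indices):
        levels = np.asarray(levels, dtype=float)
        idxs = list(idxs)
        if any(i < 0 or i >= len(levels) for i in idxs):
            raise InvalidArgumentError(f"indices {idxs} out of range for {len(levels)} levels")
        selected.append(levels[idxs])
    return build_full_grid(*selected, instances=instances)


def condition_key(p: StimulusPoint) -> tuple:
    return (p.n, round(p.size, 6), round(p.spacing, 6))


def mean_activation_patterns(
    codes_by_condition: Mapping[tuple, Sequence[np.ndarray]],
) -> tuple[np.ndarray, tuple]:
    """Average activation codes within each condition.

    Returns ``(patterns, conditions)`` with one row per condition, in
    sorted condition order.
    """
    if not codes_by_condition:
        raise InvalidArgumentError("no conditions supplied")
    conditions = tuple(sorted(codes_by_condition))
    patterns = []
    for c in conditions:
        codes = list(codes_by_condition[c])
        if not codes:
            raise InvalidArgumentError(f"condition {c} has no instances")
        patterns.append(np.mean(np.stack(codes), axis=0))
    return np.stack(patterns), conditions


def model_rdm(patterns: np.ndarray, conditions: Sequence, metric: str = "1-pearson") -> Rdm:
    """RDM with cells 1 - Pearson correlation between mean patterns."""
    patterns = np.asarray(patterns, dtype=float)
    if patterns.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 patterns")
    if np.any(patterns.std(axis=1) == 0):
        raise InvalidArgumentError("zero-variance pattern: correlation undefined")
    m = 1.0 - np.corrcoef(patterns)
    np.fill_diagonal(m, 0.0)
    m = (m + m.T) / 2.0
    return Rdm(matrix=m, conditions=tuple(conditions), metric=metric)


def categorical_rdm(feature_values: Sequence[float], conditions: Sequence, name: str = "") -> Rdm:
    """RDM with cells |log2 f_i - log2 f_j| for a single feature."""
    f = np.asarray(feature_values, dtype=float)
    if np.any(f <= 0):
        raise InvalidArgumentError("feature values must be positive")
    lf = np.log2(f)
    m = np.abs(lf[:, None] - lf[None, :])
    return Rdm(matrix=m, conditions=tuple(conditions), metric=f"log2-distance:{name}")


def rank_transform_rdm(rdm: Rdm) -> Rdm:
    """Display transform: off-diagonal cells replaced by ranks scaled to [0, 1]."""
    n = rdm.n
    i, j = np.tril_indices(n, k=-1)
    vals = rdm.matrix[i, j]
    ranks = stats.rankdata(vals)  # average ranks for ties
    if len(ranks) > 1 and ranks.max() > ranks.min():
        scaled = (ranks - ranks.min()) / (ranks.max() - ranks.min())
    else:
        scaled = np.full_like(ranks, 0.5)
    m = np.zeros((n, n))
    m[i, j] = scaled
    m += m.T
    return Rdm(matrix=m, conditions=rdm.conditions, metric=rdm.metric + "+rank")


def kendall_tau_a(rdm_a: Rdm, rdm_b: Rdm) -> float:
    """Kendall's tau-a between two RDMs' lower triangles.

    tau_a = (concordant - discordant) / (m*(m-1)/2); tied pairs count as
    neither, so ties reduce the attainable correlation.
    """
    if rdm_a.conditions != rdm_b.conditions:
        raise InvalidArgumentError("RDMs must share the same condition set")
    return _tau_a(rdm_a.lower_triangle(), rdm_b.lower_triangle())


def _tau_a(x: np.ndarray, y: np.ndarray) -> float:
    m = len(x)
    if m < 2:
        raise InvalidArgumentError("need at least 2 cells")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    i, j = np.triu_indices(m, k=1)
    s = sx[i, j] * sy[i, j]
    return float(s.sum() / (m * (m - 1) / 2))


def relatedness_test(
    seed_rdms: Sequence[Rdm],
    candidates: Mapping[str, Rdm],
    q: float = 0.01,
) -> dict[str, dict]:
    """Relate per-seed network RDMs to candidate categorical RDMs.

    For each candidate: tau-a per seed, one-sided Wilcoxon signed-rank of
    the taus against zero, then Benjamini-Hochberg FDR across candidates
    at rate ``q``.  Returns per-candidate mean tau, SEM, p, and FDR flag.
    """
    if len(seed_rdms) < 5:
        raise InvalidArgumentError("need at least 5 seed replicates")
    if not candidates:
        raise InvalidArgumentError("no candidate RDMs supplied")
    names = list(candidates)
    taus = {
        name: np.array([kendall_tau_a(r, candidates[name]) for r in seed_rdms])
        for name in names
    }
    pvals = []
    for name in names:
        t = taus[name]
        if np.allclose(t, 0.0):
            p = 1.0
        else:
            _, p = stats.wilcoxon(t, alternative="greater")
        pvals.append(p)
    from statsmodels.stats.multitest import multipletests

    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    out = {}
    for name, p, padj, rej in zip(names, pvals, p_adj, reject):
        t = taus[name]
        out[name] = {
            "tau_mean": float(t.mean()),
            "tau_sem": float(t.std(ddof=1) / np.sqrt(len(t))) if len(t) > 1 else 0.0,
            "p_value": float(p),
            "p_fdr": float(padj),
            "significant": bool(rej),
            "taus": t.tolist(),
        }
    return out


def noise_ceiling(seed_rdms: Sequence[Rdm]) -> tuple[float, float]:
    """Replicate-based bounds on the attainable RDM correlation.

    Upper bound: mean tau-a of each replicate with the grand-mean RDM
    (replicate included); lower bound: same with the replicate left out.
    """
    k = len(seed_rdms)
    if k < 2:
        raise InvalidArgumentError("need at least 2 replicates")
    conditions = seed_rdms[0].conditions
    mats = np.stack([r.matrix for r in seed_rdms])
    total = mats.sum(axis=0)
    upper, lower = [], []
    for i, r in enumerate(seed_rdms):
        mean_all = Rdm(total / k, conditions)
        mean_loo = Rdm((total - mats[i]) / (k - 1), conditions)
        upper.append(kendall_tau_a(r, mean_all))
        lower.append(kendall_tau_a(r, mean_loo))
    return float(np.mean(lower)), float(np.mean(upper))


def rdm_glm_fit(target: Rdm, predictors: Mapping[str, Rdm]) -> dict[str, float]:
    """Least-squares fit of the target RDM's lower triangle on predictor RDMs.

    Includes an intercept (reported under ``"intercept"``).  Collinear
    predictors produce a warning and a minimum-norm solution.
    """
    names = list(predictors)
    for p in predictors.values():
        if p.conditions != target.conditions:
            raise InvalidArgumentError("predictor/target condition mismatch")
    y = target.lower_triangle()
    X = np.column_stack(
        [np.ones_like(y)] + [predictors[n].lower_triangle() for n in names]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("collinear predictors: using minimum-norm solution")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    out = {"intercept": float(coef[0])}
    out.update({n: float(c) for n, c in zip(names, coef[1:])})
    return out
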