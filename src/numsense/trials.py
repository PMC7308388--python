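"""Comparison-trial construction and the synthetic observer.

A trial pairs two stimuli left/right and records the right/left ratio of
each orthogonal dimension.  Choices are simulated from a probit model
with a guessing (lapse) rate:

    P(choose right) = (1 - gamma) * (Phi(eta) - 1/2) + 1/2
    eta = b_side + b_num*log2(r_num) + b_size*log2(r_size) + b_spacing*log2(r_spacing)

which is the closed form against which the fitting stage is validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import InvalidArgumentError, SamplingInfeasibleError
from .stimulus_space import StimulusPoint

__all__ = [
    "TrialPair",
    "ChoiceDataset",
    "PAPER_RATIO_QUOTAS",
    "sample_comparison_pairs",
    "sample_uniform_pairs",
    "label_congruency",
    "simulate_observer",
    "choice_probability",
    "dataset_to_frame",
]

#: Oversampling quotas of the behavioral protocol: harder numerosity
#: ratios (closer to 1) receive more trials.
PAPER_RATIO_QUOTAS: dict[tuple[float, float], float] = {
    (0.5, 0.6): 0.10,
    (0.6, 0.7): 0.20,
    (0.7, 0.8): 0.30,
    (0.8, 0.9): 0.40,
}


@dataclass(frozen=True)
class TrialPair:
    left: StimulusPoint
    right: StimulusPoint
    pair_id: int = 0

    def __post_init__(self) -> None:
        if self.left.n == self.right.n:
            raise InvalidArgumentError("task trials require unequal numerosities")

    @property
    def r_num(self) -> float:
        return self.right.n / self.left.n

    @property
    def r_size(self) -> float:
        return self.right.size / self.left.size

    @property
    def r_spacing(self) -> float:
        return self.right.spacing / self.left.spacing

    @property
    def difficulty_ratio(self) -> float:
        """Numerosity ratio expressed as min/max, in (0, 1)."""
        return min(self.left.n, self.right.n) / max(self.left.n, self.right.n)

    @property
    def correct_side(self) -> str:
        return "right" if self.r_num > 1 else "left"


@dataclass
class ChoiceDataset:
    """Recorded choices (and optional response times) over a trial list."""

    trials: list[TrialPair]
    chosen_side: list[str]
    response_time: list[float] | None = None
    observer_id: str = "observer"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.chosen_side) != len(self.trials):
            raise InvalidArgumentError("one choice per trial required")
        if any(s not in ("left", "right") for s in self.chosen_side):
            raise InvalidArgumentError("chosen_side must be 'left' or 'right'")
        if self.response_time is not None:
            if len(self.response_time) != len(self.trials):
                raise InvalidArgumentError("one response time per trial required")
            if any(rt <= 0 for rt in self.response_time):
                raise InvalidArgumentError("response times must be positive")

    def __len__(self) -> int:
        return len(self.trials)

    def accuracy(self) -> float:
        correct = sum(
            c == t.correct_side for c, t in zip(self.chosen_side, self.trials)
        )
        return correct / len(self.trials)


def label_congruency(pair: TrialPair) -> dict[str, str]:
    """Congruency of Size and Spacing with the numerosity change.

    A dimension is congruent when it varies in the same direction as
    numerosity, incongruent when opposite, neutral when unchanged.
    """
    sign_num = math.copysign(1.0, math.log(pair.r_num))
    flags = {}
    for dim, r in (("size", pair.r_size), ("spacing", pair.r_spacing)):
        if r == 1.0:
            flags[dim] = "neutral"
        elif math.copysign(1.0, math.log(r)) == sign_num:
            flags[dim] = "congruent"
        else:
            flags[dim] = "incongruent"
    return flags


def _randomize_sides(
    a: StimulusPoint, b: StimulusPoint, pair_id: int, rng: np.random.Generator
) -> TrialPair:
    if rng.random() < 0.5:
        a, b = b, a
    return TrialPair(left=a, right=b, pair_id=pair_id)


def sample_comparison_pairs(
    dataset: Sequence[StimulusPoint],
    n_pairs: int,
    quotas: Mapping[tuple[float, float], float] = PAPER_RATIO_QUOTAS,
    rng: np.random.Generator | None = None,
) -> list[TrialPair]:
    """Sample pairs with exact per-ratio-bin counts.

    Each quota maps a half-open numerosity-ratio bin ``[lo, hi)`` (ratio
    as min/max) to the fraction of pairs it must receive; fractions must
    sum to 1 and ``fraction * n_pairs`` must be integral.
    """
    rng = np.random.default_rng() if rng is None else rng
    total = sum(quotas.values())
    if abs(total - 1.0) > 1e-9:
        raise InvalidArgumentError(f"quota fractions sum to {total}, expected 1")
    counts = {}
    for bin_, frac in quotas.items():
        c = frac * n_pairs
        if abs(c - round(c)) > 1e-9:
            raise InvalidArgumentError(
                f"quota {frac} x {n_pairs} pairs is not an integer count"
            )
        counts[bin_] = int(round(c))

    by_n: dict[int, list[StimulusPoint]] = {}
    for p in dataset:
        by_n.setdefault(p.n, []).append(p)
    levels = sorted(by_n)

    pairs: list[TrialPair] = []
    pair_id = 0
    for (lo, hi), count in counts.items():
        eligible = [
            (a, b)
            for i, a in enumerate(levels)
            for b in levels[i + 1 :]
            if lo <= a / b < hi
        ]
        if count > 0 and not eligible:
            raise SamplingInfeasibleError(
                f"no numerosity-level pair has ratio in [{lo}, {hi})"
            )
        for _ in range(count):
            na, nb = eligible[rng.integers(len(eligible))]
            a = by_n[na][rng.integers(len(by_n[na]))]
            b = by_n[nb][rng.integers(len(by_n[nb]))]
            pairs.append(_randomize_sides(a, b, pair_id, rng))
            pair_id += 1
    return pairs


def sample_uniform_pairs(
    dataset: Sequence[StimulusPoint],
    n_pairs: int,
    rng: np.random.Generator | None = None,
) -> list[TrialPair]:
    """Uniform pairs without replacement of the (left, right) combination.

    Pairs with equal numerosity are rejected and resampled.
    """
    rng = np.random.default_rng() if rng is None else rng
    m = len(dataset)
    if len({p.n for p in dataset}) < 2:
        raise InvalidArgumentError("dataset needs at least 2 numerosity levels")
    if n_pairs > m * (m - 1):
        raise InvalidArgumentError(
            f"{n_pairs} pairs requested but only {m * (m - 1)} ordered pairs exist"
        )
    seen: set[tuple[int, int]] = set()
    pairs: list[TrialPair] = []
    while len(pairs) < n_pairs:
        i, j = rng.integers(m), rng.integers(m)
        if i == j or (i, j) in seen or dataset[i].n == dataset[j].n:
            continue
        seen.add((i, j))
        pairs.append(TrialPair(left=dataset[i], right=dataset[j], pair_id=len(pairs)))
    return pairs


def choice_probability(
    pair: TrialPair, betas: Sequence[float], gamma: float
) -> float:
    """Closed-form P(choose right) for one trial under the choice model."""
    b_side, b_num, b_size, b_spacing = betas
    eta = (
        b_side
        + b_num * math.log2(pair.r_num)
        + b_size * math.log2(pair.r_size)
        + b_spacing * math.log2(pair.r_spacing)
    )
    return (1.0 - gamma) * (norm.cdf(eta) - 0.5) + 0.5


def simulate_observer(
    pairs: Sequence[TrialPair],
    betas: Sequence[float],
    gamma: float = 0.0,
    rt_model: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
    observer_id: str = "synthetic",
) -> ChoiceDataset:
    """Simulate an observer's choices on ``pairs``.

    ``betas`` are ``(b_side, b_num, b_size, b_spacing)``; ``gamma`` in
    ``[0, 1)`` is the guessing rate.  If ``rt_model = (median_ms,
    sigma_log)`` is given, response times are drawn from a lognormal.
    """
    rng = np.random.default_rng() if rng is None else rng
    if not 0.0 <= gamma < 1.0:
        raise InvalidArgumentError(f"gamma must be in [0, 1), got {gamma}")
    probs = np.array([choice_probability(p, betas, gamma) for p in pairs])
    chosen = np.where(rng.random(len(pairs)) < probs, "right", "left").tolist()
    rts = None
    if rt_model is not None:
        median_ms, sigma = rt_model
        rts = (median_ms * np.exp(sigma * rng.standard_normal(len(pairs)))).tolist()
    return ChoiceDataset(
        trials=list(pairs),
        chosen_side=chosen,
        response_time=rts,
        observer_id=observer_id,
        meta={"betas": list(betas), "gamma": gamma},
    )


def dataset_to_frame(data: ChoiceDataset) -> pd.DataFrame:
    """One row per trial: ids, ratios, congruency, choice, optional RT."""
    rows = []
    for k, (t, c) in enumerate(zip(data.trials, data.chosen_side)):
        cong = label_congruency(t)
        rows.append(
            {
                "pair_id": t.pair_id,
                "n_left": t.left.n,
                "n_right": t.right.n,
                "r_num": t.r_num,
                "r_size": t.r_size,
                "r_spacing": t.r_spacing,
                "size_congruency": cong["size"],
                "spacing_congruency": cong["spacing"],
                "correct_side": t.correct_side,
                "chosen_side": c,
                "response_time": (
                    data.response_time[k] if data.response_time is not None else np.nan
                ),
                "observer_id": data.observer_id,
            }
        )
    return pd.DataFrame(rows)
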