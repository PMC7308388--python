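"""Orthogonal 3-D dot-array stimulus space.

The space has three orthogonal log-scaled dimensions:

* ``numerosity`` -- the discrete dot count ``n``;
* ``size`` -- the product of item surface area (ISA) and total surface
  area (TSA), in px^4;
* ``spacing`` -- the product of field area (FA) and sparsity, in px^4.

Every familiar continuous feature of a dot display is a log-linear
combination of the three coordinates, so each feature defines a fixed
direction (a :class:`FeatureAxis`) in the orthonormal basis
``(log2 n, log2 size, log2 spacing)``.  Those directions are what the
projection/angle analysis of fitted choice models operates on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = [
    "StimulusPoint",
    "FeatureBundle",
    "FeatureAxis",
    "FEATURE_AXES",
    "log_grid_levels",
    "numerosity_levels",
    "build_full_grid",
    "derive_features",
    "feature_axis",
    "angle_between",
    "grid_to_frame",
    "DEFAULT_NUM_RANGE",
    "DEFAULT_SIZE_RANGE",
    "DEFAULT_SPACING_RANGE",
    "DEFAULT_LEVELS",
]

#: Default dimension ranges for the full-scale space (200 x 200 px canvas).
DEFAULT_NUM_RANGE = (7.0, 28.0)
DEFAULT_SIZE_RANGE = (2.6e5, 10.4e5)
DEFAULT_SPACING_RANGE = (0.8e7, 3.2e7)
DEFAULT_LEVELS = 13


@dataclass(frozen=True)
class StimulusPoint:
    """A location in the 3-D stimulus space plus a replicate index."""

    n: int
    size: float
    spacing: float
    instance_id: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidArgumentError(f"dot count must be >= 1, got {self.n}")
        if self.size <= 0 or self.spacing <= 0:
            raise InvalidArgumentError(
                f"size and spacing must be positive, got {self.size}, {self.spacing}"
            )

    @property
    def log_coords(self) -> np.ndarray:
        """Coordinates ``(log2 n, log2 size, log2 spacing)``."""
        return np.array(
            [math.log2(self.n), math.log2(self.size), math.log2(self.spacing)]
        )


@dataclass(frozen=True)
class FeatureBundle:
    """Continuous features derived analytically from a stimulus point.

    All areas are px^2; ``coverage`` is dimensionless; ``total_perimeter``
    is px (dots are circles).
    """

    isa: float
    tsa: float
    fa: float
    sparsity: float
    coverage: float
    total_perimeter: float


@dataclass(frozen=True)
class FeatureAxis:
    """A named unit direction in the (log2 n, log2 size, log2 spacing) basis."""

    name: str
    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(d))
        if abs(norm - 1.0) > 1e-12:
            raise InvalidArgumentError(f"axis {self.name!r} is not unit-norm ({norm})")
        object.__setattr__(self, "direction", d)


def _unit(v: Sequence[float]) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    return a / np.linalg.norm(a)


# Log-linear relations:  log2 ISA = (log2 size - log2 n)/2, etc.  Each
# feature's axis is the (unnormalised) gradient of its log w.r.t. the
# orthonormal space coordinates.  Convex hull has no exact log-linear
# form; it grows with field area at fixed n, so it shares FA's direction.
_AXIS_DIRECTIONS: dict[str, tuple[float, float, float]] = {
    "numerosity": (1.0, 0.0, 0.0),
    "size": (0.0, 1.0, 0.0),
    "spacing": (0.0, 0.0, 1.0),
    "isa": (-1.0, 1.0, 0.0),
    "tsa": (1.0, 1.0, 0.0),
    "fa": (1.0, 0.0, 1.0),
    "sparsity": (-1.0, 0.0, 1.0),
    "coverage": (0.0, 1.0, -1.0),
    "total_perimeter": (3.0, 1.0, 0.0),
    "convex_hull": (1.0, 0.0, 1.0),
}

FEATURE_AXES: tuple[str, ...] = tuple(_AXIS_DIRECTIONS)


def log_grid_levels(lo: float, hi: float, k: int) -> np.ndarray:
    """Return ``k`` levels evenly spaced on a log scale between ``lo`` and ``hi``.

    ``level[i] = lo * (hi/lo)**(i/(k-1))``; endpoints are exact.
    """
    if k < 2:
        raise InvalidArgumentError(f"need at least 2 levels, got {k}")
    if lo <= 0 or hi <= 0:
        raise InvalidArgumentError("bounds must be positive")
    if not lo < hi:
        raise InvalidArgumentError(f"require lo < hi, got {lo} >= {hi}")
    i = np.arange(k)
    levels = lo * (hi / lo) ** (i / (k - 1))
    levels[0], levels[-1] = lo, hi
    return levels


def numerosity_levels(lo: float, hi: float, k: int) -> np.ndarray:
    """Log-spaced numerosity levels rounded to the nearest integer dot count."""
    return np.rint(log_grid_levels(lo, hi, k)).astype(int)


def build_full_grid(
    num_levels: Iterable[float],
    size_levels: Iterable[float],
    spacing_levels: Iterable[float],
    instances: int = 1,
) -> list[StimulusPoint]:
    """Cartesian product of the three level lists, replicated ``instances`` times.

    Numerosity levels are rounded to integer dot counts.  Each grid point
    carries instance ids ``0 .. instances-1``.
    """
    nums = [int(round(float(v))) for v in num_levels]
    sizes = [float(v) for v in size_levels]
    spacings = [float(v) for v in spacing_levels]
    if not nums or not sizes or not spacings:
        raise InvalidArgumentError("level lists must be non-empty")
    if instances < 1:
        raise InvalidArgumentError("instances must be >= 1")
    return [
        StimulusPoint(n=n, size=s, spacing=p, instance_id=i)
        for n, s, p in product(nums, sizes, spacings)
        for i in range(instances)
    ]


def derive_features(p: StimulusPoint) -> FeatureBundle:
    """Analytic continuous features of a stimulus point.

    ISA = sqrt(size/n), TSA = sqrt(size*n), FA = sqrt(spacing*n),
    sparsity = sqrt(spacing/n), coverage = sqrt(size/spacing),
    total perimeter = n * 2*sqrt(pi*ISA).
    """
    isa = math.sqrt(p.size / p.n)
    tsa = math.sqrt(p.size * p.n)
    fa = math.sqrt(p.spacing * p.n)
    sparsity = math.sqrt(p.spacing / p.n)
    coverage = math.sqrt(p.size / p.spacing)
    total_perimeter = p.n * 2.0 * math.sqrt(math.pi * isa)
    return FeatureBundle(isa, tsa, fa, sparsity, coverage, total_perimeter)


def feature_axis(name: str) -> FeatureAxis:
    """Unit direction of a named feature in the log2 space basis."""
    try:
        direction = _AXIS_DIRECTIONS[name]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown feature {name!r}; known: {sorted(_AXIS_DIRECTIONS)}"
        ) from None
    return FeatureAxis(name=name, direction=_unit(direction))


def angle_between(a: Sequence[float], b: Sequence[float]) -> float:
    """Angle in degrees between two 3-vectors, in ``[0, 180]``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise InvalidArgumentError("angle undefined for zero vectors")
    cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def grid_to_frame(points: Iterable[StimulusPoint]) -> pd.DataFrame:
    """One row per stimulus point with coordinates and derived features."""
    rows = []
    for p in points:
        f = derive_features(p)
        rows.append(
            {
                "n": p.n,
                "size": p.size,
                "spacing": p.spacing,
                "instance_id": p.instance_id,
                "isa": f.isa,
                "tsa": f.tsa,
                "fa": f.fa,
                "sparsity": f.sparsity,
                "coverage": f.coverage,
                "total_perimeter": f.total_perimeter,
            }
        )
    return pd.DataFrame(rows)
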