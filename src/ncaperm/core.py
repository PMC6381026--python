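"""CE-FDH frontiers and necessity / sufficiency effect sizes.

Necessary Condition Analysis (NCA) asks whether a minimum level of a
predictor X is *necessary* for a high level of an outcome Y.  The default
ceiling technique, Ceiling Envelopment – Free Disposal Hull (CE-FDH), draws
a non-decreasing step function through the ceiling points of an X–Y scatter
(points whose Y exceeds the Y of every point with smaller X).  The necessity
effect size is the fraction of the scope rectangle that lies empty above the
ceiling, in the upper-left corner::

    d_necessity = (empty upper-left area) / ((x_max - x_min) * (y_max - y_min))

The mirror quantity — the empty lower-right area below the floor step — is
the sufficiency effect: a large value indicates that a high X precludes a
low Y.

Conventions
-----------
The ceiling step is *left-anchored*: over the column [x_(k), x_(k+1)) the
ceiling sits at the running maximum M_k of all y with x <= x_(k).  The floor
step is *right-anchored*: over (x_(k-1), x_(k)] the floor sits at the running
minimum m_k of all y with x >= x_(k).  This is the unique pairing under which
a 180-degree rotation of the data swaps the two effects exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from ._exceptions import DegenerateScopeError, ValidationError

__all__ = [
    "XYDataSet",
    "Scope",
    "StepFrontier",
    "EffectEstimate",
    "compute_scope",
    "ceiling_frontier",
    "floor_frontier",
    "necessity_effect",
    "sufficiency_effect",
    "classify_effect",
    "rotate180",
]


@dataclass(frozen=True)
class XYDataSet:
    """Paired predictor/outcome observations.

    Parameters
    ----------
    x, y : array-like of float
        Equal-length sequences (n >= 2) of finite values.  X is typically
        ordinal (e.g. a 1..9 Likert scale) and Y continuous, but both are
        treated as real numbers.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1:
            raise ValidationError("x and y must be one-dimensional sequences")
        if x.shape[0] != y.shape[0]:
            raise ValidationError(
                f"x and y must have equal length, got {x.shape[0]} and {y.shape[0]}"
            )
        if x.shape[0] < 2:
            raise ValidationError("at least 2 observations are required")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValidationError("x and y must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def with_y(self, y: Sequence[float]) -> "XYDataSet":
        """Return a new dataset with the same x and a replacement y."""
        return XYDataSet(self.x, np.asarray(y, dtype=float))


@dataclass(frozen=True)
class Scope:
    """The evaluation rectangle over which corner areas are normalized."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise DegenerateScopeError(
                "scope must have strictly positive width and height "
                f"(got x range [{self.x_min}, {self.x_max}], "
                f"y range [{self.y_min}, {self.y_max}])"
            )

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def encloses(self, data: XYDataSet) -> bool:
        return bool(
            (data.x >= self.x_min).all()
            and (data.x <= self.x_max).all()
            and (data.y >= self.y_min).all()
            and (data.y <= self.y_max).all()
        )


@dataclass(frozen=True)
class StepFrontier:
    """A CE-FDH step frontier over the distinct x values of a dataset.

    ``levels[k]`` is the frontier height over the column anchored at
    ``xs[k]``: the running maximum (ceiling, left-anchored) or the running
    minimum from the right (floor, right-anchored).  Both orientations yield
    non-decreasing levels.
    """

    xs: np.ndarray
    levels: np.ndarray
    orientation: Literal["ceiling", "floor"]

    def level_at(self, x: float) -> float:
        """Frontier height at a point, honouring the anchoring convention."""
        xs, levels = self.xs, self.levels
        if self.orientation == "ceiling":
            # left-anchored: level of the greatest xs <= x (clamped at ends)
            k = int(np.searchsorted(xs, x, side="right")) - 1
        else:
            # right-anchored: level of the smallest xs >= x (clamped at ends)
            k = int(np.searchsorted(xs, x, side="left"))
        k = min(max(k, 0), len(xs) - 1)
        return float(levels[k])


_BENCHMARKS = (
    (0.1, "small"),
    (0.3, "medium"),
    (0.5, "large"),
)


@dataclass(frozen=True)
class EffectEstimate:
    """An empty-corner effect size with its ingredients."""

    effect: float
    corner_area: float
    scope_area: float
    side: Literal["necessity", "sufficiency"]
    label: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", classify_effect(self.effect))

    def __str__(self) -> str:  # 3 decimals matches conventional NCA reporting
        return (
            f"{self.side} effect = {self.effect:.3f} ({self.label}); "
            f"empty corner area {self.corner_area:g} / scope {self.scope_area:g}"
        )


def compute_scope(
    data: XYDataSet,
    bounds_mode: Literal["observed", "theoretical"] = "observed",
    theoretical_bounds: tuple[float, float, float, float] | Scope | None = None,
) -> Scope:
    """Determine the scope rectangle for a dataset.

    In ``observed`` mode (the NCA default) the rectangle is the bounding box
    of the data.  In ``theoretical`` mode the caller supplies
    ``(x_min, x_max, y_min, y_max)`` — e.g. the known limits of a rating
    scale — which must enclose every observation.
    """
    if bounds_mode == "observed":
        return Scope(
            float(data.x.min()), float(data.x.max()),
            float(data.y.min()), float(data.y.max()),
        )
    if bounds_mode != "theoretical":
        raise ValidationError(f"unknown bounds_mode {bounds_mode!r}")
    if theoretical_bounds is None:
        raise ValidationError("theoretical bounds_mode requires theoretical_bounds")
    scope = (
        theoretical_bounds
        if isinstance(theoretical_bounds, Scope)
        else Scope(*map(float, theoretical_bounds))
    )
    if not scope.encloses(data):
        raise ValidationError("theoretical bounds do not enclose all data points")
    return scope


def _distinct_x_extrema(data: XYDataSet, reduce: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-distinct-x max or min of y, with xs ascending."""
    order = np.argsort(data.x, kind="stable")
    xs_sorted = data.x[order]
    ys_sorted = data.y[order]
    xs, starts = np.unique(xs_sorted, return_index=True)
    ufunc = np.maximum if reduce == "max" else np.minimum
    vals = ufunc.reduceat(ys_sorted, starts)
    return xs, vals


def ceiling_frontier(data: XYDataSet) -> StepFrontier:
    """The CE-FDH ceiling: running maximum of y over ascending distinct x."""
    xs, ymax = _distinct_x_extrema(data, "max")
    levels = np.maximum.accumulate(ymax)
    return StepFrontier(xs, levels, "ceiling")


def floor_frontier(data: XYDataSet) -> StepFrontier:
    """The CE-FDH floor: running minimum of y scanned from the right."""
    xs, ymin = _distinct_x_extrema(data, "min")
    levels = np.minimum.accumulate(ymin[::-1])[::-1]
    return StepFrontier(xs, levels, "floor")


def _check_scope(data: XYDataSet, scope: Scope | None) -> Scope:
    if scope is None:
        return compute_scope(data)
    if not scope.encloses(data):
        raise ValidationError("scope does not enclose all data points")
    return scope


def necessity_effect(data: XYDataSet, scope: Scope | None = None) -> EffectEstimate:
    """Empty upper-left fraction of the scope above the CE-FDH ceiling.

    The ceiling is left-anchored, so the column [xs[k], xs[k+1]) contributes
    width * (y_max - M_k).  Under a theoretical scope wider than the data the
    first level extends left to scope.x_min and the last level extends right
    to scope.x_max (continuity of the step).
    """
    scope = _check_scope(data, scope)
    frontier = ceiling_frontier(data)
    xs, levels = frontier.xs, frontier.levels
    edges = np.concatenate(([scope.x_min], xs[1:], [scope.x_max]))
    widths = np.diff(edges)
    # heights can only be non-negative since scope encloses the data
    corner = float(np.dot(widths, scope.y_max - levels))
    return EffectEstimate(corner / scope.area, corner, scope.area, "necessity")


def sufficiency_effect(data: XYDataSet, scope: Scope | None = None) -> EffectEstimate:
    """Empty lower-right fraction of the scope below the CE-FDH floor.

    Mirror of :func:`necessity_effect` under the right-anchored floor: the
    column (xs[k-1], xs[k]] contributes width * (m_k - y_min).
    """
    scope = _check_scope(data, scope)
    frontier = floor_frontier(data)
    xs, levels = frontier.xs, frontier.levels
    edges = np.concatenate(([scope.x_min], xs[:-1], [scope.x_max]))
    widths = np.diff(edges)
    corner = float(np.dot(widths, levels - scope.y_min))
    return EffectEstimate(corner / scope.area, corner, scope.area, "sufficiency")


def classify_effect(effect: float) -> str:
    """Benchmark label for an effect size.

    Effects below 0.1 are conventionally called small, [0.1, 0.3) medium,
    [0.3, 0.5) large, and 0.5 or more very large.
    """
    if not (0.0 <= effect <= 1.0):
        raise ValidationError(f"effect must lie in [0, 1], got {effect}")
    for upper, label in _BENCHMARKS:
        if effect < upper:
            return label
    return "very large"


def rotate180(data: XYDataSet, scope: Scope | None = None) -> XYDataSet:
    """Rotate a dataset 180 degrees about the centre of its scope.

    Maps (x, y) to (x_min + x_max - x, y_min + y_max - y).  The rotation
    swaps the upper-left and lower-right corners, so the sufficiency effect
    of the original equals the necessity effect of the rotated data.
    """
    scope = _check_scope(data, scope)
    return XYDataSet(
        scope.x_min + scope.x_max - data.x,
        scope.y_min + scope.y_max - data.y,
    )
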