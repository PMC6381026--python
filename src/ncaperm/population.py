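"""Constrained-uniform populations with known true necessity and sufficiency.

A population is a band in the [1, 9] x [1, 9] square.  X takes the integer
levels 1..9 with equal probability; given X = x, Y is uniform on
[L(x), U(x)], where the envelope is fixed by two integers:

* ``u`` — the upper Y-limit at X = 1.  The upper limit rises by 1 per X step
  until it hits 9: ``U(x) = min(u + x - 1, 9)``.  The empty staircase above
  U is the *true necessity effect* N(u) = sum_{x=1..8} (9 - U(x)) / 64.
* ``l`` — the lower Y-limit at X = 9.  Scanning leftwards the lower limit
  falls by 1 per step until it hits 1: ``L(x) = max(l - (9 - x), 1)``.  The
  empty staircase below L is the *true sufficiency effect*
  S(l) = sum_{x=2..9} (L(x) - 1) / 64.

The 81 (u, l) pairs give all combinations of N, S in
{0, 0.016, 0.047, 0.094, 0.156, 0.234, 0.328, 0.438, 0.563}.  The
construction is 180-degree rotation symmetric: S(l) = N(10 - l).

u = 1, l = 9 degenerates to the deterministic line Y = X and is permitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from ._exceptions import ValidationError
from .core import XYDataSet

__all__ = [
    "PopulationSpec",
    "envelope_limits",
    "true_necessity_effect",
    "true_sufficiency_effect",
    "sample_population",
]

X_LEVELS = np.arange(1, 10)
Y_MIN, Y_MAX = 1.0, 9.0
SCOPE_AREA = (9 - 1) * (9 - 1)

#: hook signature: (rng, low, high, size) -> samples in [low, high]
YSampler = Callable[[np.random.Generator, np.ndarray, np.ndarray, int], np.ndarray]


def _uniform_sampler(
    rng: np.random.Generator, low: np.ndarray, high: np.ndarray, size: int
) -> np.ndarray:
    return rng.uniform(low, high, size)


def _check_limit(name: str, value: int) -> int:
    if not (isinstance(value, (int, np.integer)) and 1 <= value <= 9):
        raise ValidationError(f"{name} must be an integer in 1..9, got {value!r}")
    return int(value)


@dataclass(frozen=True)
class PopulationSpec:
    """Envelope parameters: upper limit ``u`` at X = 1, lower limit ``l`` at X = 9."""

    u: int = 9
    l: int = 1

    def __post_init__(self) -> None:
        _check_limit("u", self.u)
        _check_limit("l", self.l)

    @property
    def true_necessity(self) -> float:
        return true_necessity_effect(self.u)

    @property
    def true_sufficiency(self) -> float:
        return true_sufficiency_effect(self.l)


def envelope_limits(spec: PopulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Upper and lower Y-limits (U(x), L(x)) for x = 1..9."""
    upper = np.minimum(spec.u + X_LEVELS - 1, 9).astype(float)
    lower = np.maximum(spec.l - (9 - X_LEVELS), 1).astype(float)
    return upper, lower


def true_necessity_effect(u: int) -> float:
    """Closed-form population necessity effect for upper limit ``u`` at X = 1.

    The empty upper-left staircase has unit-column area 9 - U(x) over each
    column [x, x+1), x = 1..8; the scope is the full 8 x 8 square.
    Decreases from 36/64 = 0.5625 at u = 1 to 0 at u = 9.
    """
    u = _check_limit("u", u)
    upper = np.minimum(u + X_LEVELS - 1, 9)
    return float((9 - upper[:-1]).sum() / SCOPE_AREA)


def true_sufficiency_effect(l: int) -> float:
    """Closed-form population sufficiency effect for lower limit ``l`` at X = 9.

    Mirror of :func:`true_necessity_effect` under 180-degree rotation:
    the lower-right staircase has column area L(x) - 1 over (x-1, x],
    x = 2..9.  Increases from 0 at l = 1 to 36/64 = 0.5625 at l = 9.
    """
    l = _check_limit("l", l)
    lower = np.maximum(l - (9 - X_LEVELS), 1)
    return float((lower[1:] - 1).sum() / SCOPE_AREA)


def sample_population(
    spec: PopulationSpec,
    n_per_x: int,
    seed: int | np.random.Generator | None = None,
    y_sampler: YSampler = _uniform_sampler,
) -> XYDataSet:
    """Draw a balanced sample of virtual subjects from the population.

    Each X level 1..9 receives exactly ``n_per_x`` subjects (total
    N = 9 * n_per_x, so the study's N range 18..495 corresponds to
    n_per_x 2..55); each subject's Y is drawn independently from
    ``y_sampler`` on [L(x), U(x)] (uniform by default; a point mass where
    the envelope pinches to L = U).  Samples are clipped into the envelope
    to guard against float rounding at the boundary.
    """
    if n_per_x < 1:
        raise ValidationError(f"n_per_x must be >= 1, got {n_per_x}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    upper, lower = envelope_limits(spec)
    x = np.repeat(X_LEVELS, n_per_x).astype(float)
    low = np.repeat(lower, n_per_x)
    high = np.repeat(upper, n_per_x)
    y = np.clip(y_sampler(rng, low, high, x.shape[0]), low, high)
    return XYDataSet(x, y)
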