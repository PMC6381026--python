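"""Permutation significance test for the CE-FDH necessity effect.

The test reshuffles the outcome Y (but not X) without replacement many
times, recomputes the necessity effect after each reshuffle, and reports
the p-value as the proportion of reshuffled effects that are equal to or
stronger than the observed effect.

Because X is fixed and the y multiset is conserved, the observed-scope
rectangle is identical across reshuffles; it is computed once and reused.

A mechanistic diagnostic, :func:`permutable_fraction`, reports the share of
points that sit strictly above the ceiling level at the smallest X — the
only points that a reshuffle can move into the empty upper-left corner and
thereby weaken the observed effect.  The larger this share, the smaller the
reshuffled effects tend to be and the smaller the p-value; a strong floor
(high sufficiency) inflates it, which is the mechanism behind the test's
type-I inflation under sufficiency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as _iter_permutations

import numpy as np

from ._exceptions import ValidationError
from .core import Scope, XYDataSet, ceiling_frontier, compute_scope, necessity_effect

__all__ = [
    "PermutationResult",
    "permute_outcome",
    "permutation_test",
    "pvalue_from_reshuffles",
    "exhaustive_permutation_test",
    "permutable_fraction",
]

#: absolute tolerance absorbing float noise when comparing area fractions
TIE_TOL = 1e-12

#: factorial-enumeration guard for the exhaustive test
MAX_EXHAUSTIVE_N = 8


@dataclass(frozen=True)
class PermutationResult:
    """Observed effect, reshuffled-effect distribution, and p-value."""

    observed_effect: float
    permuted_effects: np.ndarray
    p_value: float
    n_permutations: int
    seed: int | None = None
    exact: bool = False

    def __str__(self) -> str:
        kind = "exact" if self.exact else f"{self.n_permutations} permutations"
        return (
            f"necessity effect = {self.observed_effect:.3f}, "
            f"p = {self.p_value:.3f} ({kind})"
        )


class _NecessityEngine:
    """Vectorized necessity-effect evaluation for many y-reshuffles at once.

    Precomputes the x ordering, the distinct-x group boundaries, and the
    column widths; each batch of reshuffled y rows then needs only a grouped
    max, a running max, and a dot product.
    """

    def __init__(self, data: XYDataSet, scope: Scope):
        self.order = np.argsort(data.x, kind="stable")
        xs_sorted = data.x[self.order]
        self.xs, self.starts = np.unique(xs_sorted, return_index=True)
        edges = np.concatenate(([scope.x_min], self.xs[1:], [scope.x_max]))
        self.widths = np.diff(edges)
        self.scope = scope

    def effects(self, y_rows: np.ndarray) -> np.ndarray:
        """Necessity effects for each row of ``y_rows`` (shape k x n)."""
        grouped = np.maximum.reduceat(y_rows[:, self.order], self.starts, axis=1)
        levels = np.maximum.accumulate(grouped, axis=1)
        corner = (self.scope.y_max - levels) @ self.widths
        return corner / self.scope.area


def permute_outcome(data: XYDataSet, rng: np.random.Generator) -> XYDataSet:
    """Reshuffle y uniformly at random (sampling without replacement)."""
    return data.with_y(rng.permutation(data.y))


def _resolve_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def permutation_test(
    data: XYDataSet,
    n_permutations: int = 1000,
    seed: int | np.random.Generator | None = None,
    scope: Scope | None = None,
    plus_one: bool = False,
) -> PermutationResult:
    """Monte-Carlo permutation test of the CE-FDH necessity effect.

    Parameters
    ----------
    n_permutations
        Number of independent random reshuffles (default 1000).  Draws are
        independent, so repeats can occur, as in standard permutation-test
        practice.
    seed
        Integer seed or a ``numpy.random.Generator`` to draw from.
    scope
        Evaluation rectangle; defaults to the observed bounding box, which
        is invariant under reshuffling.
    plus_one
        If True, count the observed arrangement itself in both numerator
        and denominator ((b + 1) / (m + 1)); a conservative variant that
        guarantees p > 0.  The default (False) is the plain proportion.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    scope = compute_scope(data) if scope is None else scope
    observed = necessity_effect(data, scope).effect

    rng = _resolve_rng(seed)
    y = data.y
    perms = np.empty((n_permutations, y.shape[0]))
    for i in range(n_permutations):
        perms[i] = rng.permutation(y)
    effects = _NecessityEngine(data, scope).effects(perms)

    return PermutationResult(
        observed_effect=observed,
        permuted_effects=effects,
        p_value=_proportion_ge(effects, observed, plus_one),
        n_permutations=n_permutations,
        seed=seed if isinstance(seed, int) else None,
    )


def pvalue_from_reshuffles(
    data: XYDataSet,
    reshuffled_y: np.ndarray,
    scope: Scope | None = None,
    plus_one: bool = False,
) -> PermutationResult:
    """Permutation test with an explicitly supplied set of reshuffles.

    ``reshuffled_y`` has one reshuffled y vector per row; each row must be a
    rearrangement of the observed y multiset.  Useful for worked examples
    where the reshuffles are given, and for validating against enumeration.
    """
    reshuffled_y = np.asarray(reshuffled_y, dtype=float)
    if reshuffled_y.ndim != 2 or reshuffled_y.shape[1] != data.n:
        raise ValidationError("reshuffled_y must have shape (k, n)")
    ref = np.sort(data.y)
    for i, row in enumerate(reshuffled_y):
        if not np.allclose(np.sort(row), ref):
            raise ValidationError(f"row {i} is not a rearrangement of the observed y")
    scope = compute_scope(data) if scope is None else scope
    observed = necessity_effect(data, scope).effect
    effects = _NecessityEngine(data, scope).effects(reshuffled_y)
    return PermutationResult(
        observed_effect=observed,
        permuted_effects=effects,
        p_value=_proportion_ge(effects, observed, plus_one),
        n_permutations=reshuffled_y.shape[0],
    )


def exhaustive_permutation_test(
    data: XYDataSet, scope: Scope | None = None
) -> PermutationResult:
    """Exact permutation test by enumerating all n! reorderings of y.

    Enumerates every ordering (duplicate y values make some orderings
    coincide; weighting them equally still yields the exact multiset
    p-value).  Guarded at n <= 8 (8! = 40320 evaluations).
    """
    if data.n > MAX_EXHAUSTIVE_N:
        raise ValidationError(
            f"exhaustive enumeration limited to n <= {MAX_EXHAUSTIVE_N}, "
            f"got n = {data.n}"
        )
    scope = compute_scope(data) if scope is None else scope
    observed = necessity_effect(data, scope).effect
    all_orders = np.array(list(_iter_permutations(data.y)), dtype=float)
    effects = _NecessityEngine(data, scope).effects(all_orders)
    return PermutationResult(
        observed_effect=observed,
        permuted_effects=effects,
        p_value=_proportion_ge(effects, observed, plus_one=False),
        n_permutations=math.factorial(data.n),
        exact=True,
    )


def permutable_fraction(data: XYDataSet) -> float:
    """Share of points strictly above the ceiling level at the smallest X.

    Only these points can be reshuffled into the empty upper-left corner;
    every other point, wherever its X lands, stays at or below the ceiling's
    first step and leaves the corner empty.
    """
    compute_scope(data)  # raises on degenerate data
    first_level = ceiling_frontier(data).levels[0]
    return float(np.mean(data.y > first_level))


def _proportion_ge(effects: np.ndarray, observed: float, plus_one: bool) -> float:
    b = int(np.count_nonzero(effects >= observed - TIE_TOL))
    m = effects.shape[0]
    return (b + 1) / (m + 1) if plus_one else b / m
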