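"""Scope, CE-FDH frontiers, and the two empty-corner effect sizes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncaperm import (
    DegenerateScopeError,
    Scope,
    ValidationError,
    XYDataSet,
    ceiling_frontier,
    classify_effect,
    compute_scope,
    floor_frontier,
    necessity_effect,
    rotate180,
    sufficiency_effect,
)

FULL_SCOPE = Scope(1, 9, 1, 9)


# ---------------------------------------------------------------- datasets

def test_dataset_validation_rejects_bad_shapes():
    with pytest.raises(ValidationError):
        XYDataSet([1.0], [2.0])  # n < 2
    with pytest.raises(ValidationError):
        XYDataSet([1.0, 2.0], [1.0])  # unequal length
    with pytest.raises(ValidationError):
        XYDataSet([1.0, np.inf], [1.0, 2.0])  # non-finite


# ------------------------------------------------------------------- scope

def test_observed_scope_of_full_square_has_area_64(upper_trace):
    assert compute_scope(upper_trace).area == 64.0


def test_observed_scope_of_worked_example(worked_example):
    observed, _ = worked_example
    scope = compute_scope(observed)
    assert (scope.x_min, scope.x_max, scope.y_min, scope.y_max) == (1, 3, 1, 10)
    assert scope.area == 18.0


def test_degenerate_scope_raises():
    flat = XYDataSet([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
    with pytest.raises(DegenerateScopeError):
        compute_scope(flat)
    with pytest.raises(DegenerateScopeError):
        necessity_effect(flat)


def test_theoretical_scope_must_enclose_data():
    data = XYDataSet([1.0, 2.0], [1.0, 10.0])
    with pytest.raises(ValidationError):
        compute_scope(data, "theoretical", (1, 2, 1, 9))
    wide = compute_scope(data, "theoretical", (0, 5, 0, 12))
    assert wide.area == 60.0


# --------------------------------------------------------------- frontiers

def test_ceiling_levels_are_running_maxima(worked_example):
    observed, _ = worked_example
    frontier = ceiling_frontier(observed)
    assert frontier.xs.tolist() == [1, 2, 3]
    assert frontier.levels.tolist() == [7, 10, 10]


@pytest.mark.parametrize(
    "y, expected",
    [
        ([4.0] * 5, [4.0]),  # single distinct y: constant frontier
        (list(range(1, 6)), [1.0, 2.0, 3.0, 4.0, 5.0]),  # y = x: all ceiling points
    ],
)
def test_ceiling_frontier_edge_shapes(y, expected):
    data = XYDataSet(np.arange(1.0, len(y) + 1), y)
    levels = ceiling_frontier(data).levels
    if len(expected) == 1:
        assert np.all(levels == expected[0])
    else:
        assert levels.tolist() == expected


def test_floor_levels_match_stated_lower_limits(lower_trace):
    frontier = floor_frontier(lower_trace)
    assert frontier.levels.tolist() == [1, 1, 1, 1, 1, 2, 3, 4, 5]


def test_floor_is_reflected_ceiling(worked_example):
    observed, _ = worked_example
    rotated = rotate180(observed)
    floor = floor_frontier(observed)
    ceil_rot = ceiling_frontier(rotated)
    scope = compute_scope(observed)
    # reflect the rotated ceiling back into original coordinates
    assert np.allclose(
        floor.levels, (scope.y_min + scope.y_max - ceil_rot.levels)[::-1]
    )


def test_frontier_levels_nondecreasing_and_in_range(worked_example):
    observed, _ = worked_example
    for frontier in (ceiling_frontier(observed), floor_frontier(observed)):
        assert np.all(np.diff(frontier.levels) >= 0)
        assert frontier.levels.min() >= observed.y.min()
        assert frontier.levels.max() <= observed.y.max()


# ----------------------------------------------------------------- effects

def test_necessity_effect_matches_envelope_arithmetic(upper_trace):
    est = necessity_effect(upper_trace)
    assert est.corner_area == 21.0
    assert est.scope_area == 64.0
    assert est.effect == pytest.approx(21 / 64)
    assert round(est.effect, 3) == 0.328


def test_sufficiency_effect_matches_envelope_arithmetic(lower_trace):
    est = sufficiency_effect(lower_trace)
    assert est.corner_area == 10.0
    assert est.effect == pytest.approx(10 / 64)
    assert round(est.effect, 3) == 0.156


def test_worked_example_observed_effect(worked_example):
    observed, _ = worked_example
    assert necessity_effect(observed).effect == pytest.approx(3 / 18)


def test_worked_example_permutation_effects_row(worked_example):
    _, perms = worked_example
    printed = [0.000, 0.000, 0.333, 0.444, 0.000, 0.000, 0.167, 0.333, 0.000, 0.000]
    computed = [round(necessity_effect(p).effect, 3) for p in perms]
    assert computed == printed


def test_corner_vanishes_when_extreme_corner_point_present():
    # a point at (x_min, y_max) pins the ceiling at the top from the start
    data = XYDataSet([1.0, 2.0, 3.0], [9.0, 2.0, 5.0])
    assert necessity_effect(data).effect == 0.0
    # mirror: (x_max, y_min) pins the floor at the bottom
    data2 = XYDataSet([1.0, 2.0, 3.0], [5.0, 2.0, 1.0])
    assert sufficiency_effect(data2).effect == 0.0


def test_theoretical_scope_extends_edge_strips():
    # data inside [2,4]x[2,4]; widening the scope adds empty margin columns
    data = XYDataSet([2.0, 3.0, 4.0], [2.0, 3.0, 4.0])
    est = necessity_effect(data, compute_scope(data, "theoretical", (1, 9, 1, 9)))
    # columns: [1,2)->M=2, [2,3)->2, [3,4)->3, [4,9)->4 against y_max 9
    assert est.corner_area == (9 - 2) + (9 - 2) + (9 - 3) + 5 * (9 - 4)
    assert est.scope_area == 64


# ----------------------------------------------------------- classification

@pytest.mark.parametrize(
    "effect, label",
    [
        (0.0, "small"),
        (0.099, "small"),
        (0.1, "medium"),
        (0.167, "medium"),
        (0.3, "large"),
        (0.328, "large"),
        (0.5, "very large"),
        (0.563, "very large"),
        (1.0, "very large"),
    ],
)
def test_benchmark_labels(effect, label):
    assert classify_effect(effect) == label


def test_classify_rejects_out_of_range():
    with pytest.raises(ValidationError):
        classify_effect(-0.01)
    with pytest.raises(ValidationError):
        classify_effect(1.01)


# ------------------------------------------------------ property tests

def _datasets(min_size=3, max_size=20):
    finite = st.floats(0.0, 100.0, allow_nan=False)
    return st.lists(
        st.tuples(finite, finite), min_size=min_size, max_size=max_size
    ).filter(
        lambda pts: len({p[0] for p in pts}) >= 2 and len({p[1] for p in pts}) >= 2
    ).map(lambda pts: XYDataSet(*map(np.array, zip(*pts))))


@settings(derandomize=True, max_examples=150)
@given(_datasets())
def test_effects_bounded_in_unit_interval(data):
    assert 0.0 <= necessity_effect(data).effect <= 1.0
    assert 0.0 <= sufficiency_effect(data).effect <= 1.0


@settings(derandomize=True, max_examples=150)
@given(_datasets())
def test_rotation_duality_exact(data):
    """Rotating the scatter 180 degrees swaps the two empty corners."""
    assert sufficiency_effect(data).effect == pytest.approx(
        necessity_effect(rotate180(data)).effect, abs=1e-12
    )


def test_rotation_duality_on_worked_example(worked_example):
    observed, _ = worked_example
    assert sufficiency_effect(observed).effect == pytest.approx(
        necessity_effect(rotate180(observed)).effect
    )


@settings(derandomize=True, max_examples=100)
@given(
    _datasets(),
    st.floats(0.0, 1.0, allow_nan=False),
    st.floats(0.0, 100.0, allow_nan=False),
)
def test_adding_a_point_never_increases_necessity(data, tx, py):
    """Under a fixed scope, a point added within the dataset's x-range can
    only raise the ceiling and shrink the empty corner.  (A point *outside*
    the x-range is excluded: the ceiling line is extended horizontally to
    the scope edge, so a low-y point extending the range leftwards can lower
    the extended strip and legitimately enlarge the corner.)"""
    scope = Scope(-1, 101, -1, 101)
    px = data.x.min() + tx * (data.x.max() - data.x.min())
    before = necessity_effect(data, scope).effect
    bigger = XYDataSet(np.r_[data.x, px], np.r_[data.y, py])
    after = necessity_effect(bigger, scope).effect
    assert after <= before + 1e-12


def _brute_force_empty_cells(data):
    """Count empty unit cells above the ceiling by exhaustive enumeration.

    A cell [cx, cx+1) x [cy, cy+1) inside the observed scope lies above the
    ceiling iff no data point with x <= cx has y > cy.
    """
    x0, x1 = int(data.x.min()), int(data.x.max())
    y0, y1 = int(data.y.min()), int(data.y.max())
    count = 0
    for cx in range(x0, x1):
        for cy in range(y0, y1):
            if not np.any((data.x <= cx) & (data.y > cy)):
                count += 1
    return count


@settings(derandomize=True, max_examples=100)
@given(
    st.lists(
        st.tuples(st.integers(0, 8), st.integers(0, 8)), min_size=3, max_size=15
    ).filter(
        lambda pts: len({p[0] for p in pts}) >= 2 and len({p[1] for p in pts}) >= 2
    )
)
def test_corner_area_equals_brute_force_cell_count(points):
    data = XYDataSet(*map(np.array, map(list, zip(*points))))
    est = necessity_effect(data)
    assert est.corner_area == pytest.approx(_brute_force_empty_cells(data))
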