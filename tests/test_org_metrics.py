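import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import array_shapes, arrays

from foragescan.org_metrics import (best_r, count_intersections,
                                    intersection_rate, mean_itd,
                                    optimal_open_path, pao, path_length,
                                    score_sequence)

# ---------------------------------------------------------------------------
# strategies

coords_strategy = arrays(
    float, array_shapes(min_dims=2, max_dims=2, min_side=3, max_side=12)
    .filter(lambda s: s[1] == 2),
    elements=st.floats(-1000, 1000, allow_nan=False),
)


def _coords(n_min=3, n_max=10):
    return st.integers(n_min, n_max).flatmap(
        lambda n: arrays(float, (n, 2),
                         elements=st.floats(-1000, 1000, allow_nan=False)))


# ---------------------------------------------------------------------------
# best-r


@pytest.mark.parametrize("coords,expected", [
    ([(0, 7), (1, 3), (2, 9), (3, 1)], 1.0),      # x linear in pick order
    ([(0, 5), (2, 5), (1, 5), (3, 5)], 0.8),      # hand Pearson: r_x = 4/5
])
def test_best_r_known_values(coords, expected):
    assert best_r(coords) == pytest.approx(expected)


def test_best_r_too_few_picks_undefined():
    assert math.isnan(best_r([(0, 0), (1, 1)]))


def test_best_r_single_axis_variance_uses_defined_axis():
    # x constant: only y correlates; perfect vertical sweep -> 1
    assert best_r([(5, 0), (5, 10), (5, 20)]) == pytest.approx(1.0)
    # both constant -> undefined
    assert math.isnan(best_r([(5, 5), (5, 5), (5, 5)]))


@settings(deadline=None, max_examples=50)
@given(_coords())
def test_best_r_range_and_symmetries(c):
    """best-r lies in [0,1]; invariant to axis reflection and x<->y swap."""
    r = best_r(c)
    if math.isnan(r):
        return
    assert 0.0 <= r <= 1.0 + 1e-12
    assert best_r(c * np.array([-1.0, 1.0])) == pytest.approx(r)
    assert best_r(c * np.array([1.0, -1.0])) == pytest.approx(r)
    assert best_r(c[:, ::-1]) == pytest.approx(r)


# ---------------------------------------------------------------------------
# mean ITD


@pytest.mark.parametrize("coords,expected", [
    ([(0, 0), (3, 4)], 5.0),
    ([(0, 0), (3, 4), (3, 8)], 4.5),
])
def test_mean_itd_known_values(coords, expected):
    assert mean_itd(coords) == pytest.approx(expected)


def test_mean_itd_single_pick_undefined():
    assert math.isnan(mean_itd([(1, 1)]))


@settings(deadline=None, max_examples=50)
@given(_coords(n_min=2), st.floats(-500, 500), st.floats(-500, 500))
def test_mean_itd_translation_invariant(c, dx, dy):
    assert mean_itd(c + np.array([dx, dy])) == pytest.approx(
        mean_itd(c), abs=1e-6)


# ---------------------------------------------------------------------------
# optimal open path


def test_collinear_optimal_is_span():
    pts = [(0, 0), (5, 0), (2, 0), (9, 0)]
    sol = optimal_open_path(pts, mode="exact")
    assert sol.length == pytest.approx(9.0)


def test_unit_square_optimal_open_path():
    sol = optimal_open_path([(0, 0), (1, 0), (1, 1), (0, 1)], mode="exact")
    assert sol.length == pytest.approx(3.0)
    assert sol.method == "exact_dp"


def test_single_point_degenerate():
    sol = optimal_open_path([(3, 3)])
    assert sol.length == 0.0 and sol.method == "degenerate"
    with pytest.raises(ValueError):
        optimal_open_path(np.empty((0, 2)))


def _brute_force_open_path(coords):
    coords = np.asarray(coords, float)
    best = math.inf
    for perm in itertools.permutations(range(len(coords))):
        best = min(best, path_length(coords[list(perm)]))
    return best


def test_exact_equals_brute_force_and_heuristic_bounds(rng):
    """On random small instances the DP is exactly optimal and the
    nearest-neighbour + 2-opt heuristic never beats it."""
    for _ in range(30):
        n = int(rng.integers(4, 8))
        c = rng.uniform(0, 100, (n, 2))
        exact = optimal_open_path(c, mode="exact").length
        brute = _brute_force_open_path(c)
        heur = optimal_open_path(c, mode="heuristic").length
        assert exact == pytest.approx(brute, rel=1e-12)
        assert heur >= exact - 1e-9


def test_solution_length_matches_permutation(rng):
    c = rng.uniform(0, 100, (7, 2))
    sol = optimal_open_path(c, mode="exact")
    assert path_length(c[sol.order_permutation]) == pytest.approx(sol.length)


# ---------------------------------------------------------------------------
# PAO


@pytest.mark.parametrize("ratio,expected", [(1.1, 10.0), (1.5, 50.0),
                                            (2.0, 100.0)])
def test_pao_worked_ratios(ratio, expected):
    """Collinear constructions whose realized length is a known multiple
    of the exact optimum."""
    if ratio == 2.0:
        pts = [(0, 0), (3, 0), (1, 0), (2, 0)]  # 3+2+1 = 6, optimum 3
    else:
        c = 1.0 - (ratio - 1.0)
        pts = [(0, 0), (1, 0), (c, 0)]          # 1 + (1-c), optimum 1
    assert pao(pts) == pytest.approx(expected)


def test_pao_optimal_order_is_zero():
    assert pao([(0, 0), (4, 0), (9, 0)]) == pytest.approx(0.0)


def test_pao_degenerate_geometry_undefined():
    assert math.isnan(pao([(1, 1)] * 5))


def test_pao_clamp_keeps_nonnegative(rng):
    """Even when the heuristic solver is in play, PAO >= 0 always."""
    for _ in range(10):
        c = rng.uniform(0, 1000, (15, 2))  # heuristic regime (n > 10)
        assert pao(c) >= 0.0


@settings(deadline=None, max_examples=30)
@given(_coords(n_min=3, n_max=8), st.floats(0.1, 10))
def test_pao_scale_invariant(c, s):
    p = pao(c)
    if math.isnan(p):
        return
    assert pao(c * s) == pytest.approx(p, abs=1e-6)


def test_rigid_motion_invariance(rng):
    """mean ITD, PAO and crossings are unchanged by rotation+translation."""
    c = rng.uniform(0, 100, (8, 2))
    th = 0.83
    R = np.array([[math.cos(th), -math.sin(th)],
                  [math.sin(th), math.cos(th)]])
    c2 = c @ R.T + np.array([37.0, -11.0])
    assert mean_itd(c2) == pytest.approx(mean_itd(c))
    assert pao(c2) == pytest.approx(pao(c), abs=1e-8)
    assert count_intersections(c2) == count_intersections(c)


# ---------------------------------------------------------------------------
# intersections


def test_bowtie_has_one_crossing():
    pts = [(0, 0), (1, 1), (1, 0), (0, 1)]
    assert count_intersections(pts) == 1
    assert intersection_rate(pts) == pytest.approx(0.25)


def test_pentagram_order_has_three_crossings():
    """Open path visiting every 2nd vertex of a regular pentagon: its 4
    segments admit 3 non-adjacent pairs, all crossing (brute-force oracle)."""
    ang = [math.pi / 2 + 2 * math.pi * k / 5 for k in (0, 2, 4, 1, 3)]
    pts = [(math.cos(a), math.sin(a)) for a in ang]
    assert count_intersections(pts) == 3


def test_monotone_scan_has_no_crossings(rng):
    xs = np.sort(rng.uniform(0, 100, 10))
    ys = rng.uniform(0, 100, 10)
    pts = np.column_stack([xs, ys])
    assert count_intersections(pts) == 0
    assert intersection_rate(pts) == 0.0


def test_fewer_than_four_picks_zero_by_convention():
    assert count_intersections([(0, 0), (1, 1), (2, 0)]) == 0


def test_collinear_overlap_counts_once():
    # segments 1 (0->10) and 3 (4->2) overlap on the x-axis
    pts = [(0, 0), (10, 0), (4, 5), (4, 0), (2, 0)]
    assert count_intersections([(0, 0), (10, 0), (4, 5), (4, 0)]) == 1
    assert count_intersections(pts) >= 1


def test_vertex_touch_counts_once():
    # segment 3 passes exactly through the shared vertex of segments 1-2
    pts = [(0, 0), (2, 2), (4, 0), (2, 4), (2, 0)]
    assert count_intersections(pts) >= 1


# ---------------------------------------------------------------------------
# score bundle


def test_two_pick_trial_only_itd_defined(trial_factory):
    sc = score_sequence(trial_factory([(0, 0), (3, 4)]).picks)
    assert sc.mean_itd == pytest.approx(5.0)
    assert sc.best_r is None and sc.pao is None
    assert sc.intersection_rate is None
    assert sc.reasons["best_r"] == "too_few_picks"


def test_ten_pick_scanner_all_defined(trial_factory):
    coords = [(i * 100, 50 + 10 * (i % 2)) for i in range(10)]
    sc = score_sequence(trial_factory(coords).picks)
    assert None not in (sc.best_r, sc.mean_itd, sc.pao, sc.intersection_rate)
    assert sc.best_r > 0.99
    assert sc.intersection_rate == 0.0


def test_whole_trial_scores_match_direct_calls(rng, trial_factory):
    c = rng.uniform(0, 500, (9, 2))
    sc = score_sequence(trial_factory(c).picks)
    assert sc.best_r == pytest.approx(best_r(c))
    assert sc.mean_itd == pytest.approx(mean_itd(c))
    assert sc.pao == pytest.approx(pao(c))
    assert sc.intersection_rate == pytest.approx(intersection_rate(c))
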