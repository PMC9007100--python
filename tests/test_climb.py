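import numpy as np
import pytest

from _oracles import climb_dp_oracle
from conftest import random_map
from spinedef import Spine, SpineMap, TrunkSurface
from spinedef.climb import (
    ClimbConfig,
    ClimbPath,
    InvalidPathError,
    best_path_at_level,
    climb_sweep,
    evaluate_path_costs,
    optimize_climb,
    path_cost,
)

FAST = ClimbConfig(paths_per_level=2000, seed=1)


def vertical(x, H=30.0):
    return ClimbPath(np.array([x, x]), np.array([0.0, H]))


def test_path_cost_examples(surface30, empty_map):
    assert path_cost(empty_map, vertical(5.0), 2.0, FAST) == pytest.approx(30.0)
    one = SpineMap.from_spines(surface30, [Spine(5.0, 15.0)])
    assert path_cost(one, vertical(5.0), 2.0, FAST) == pytest.approx(40.0)
    # 3-4-5 diagonal on a 4-cm-tall spotless segment
    seg = SpineMap.empty(TrunkSurface(30.0, 4.0))
    diag = ClimbPath(np.array([0.0, 3.0]), np.array([0.0, 4.0]))
    assert path_cost(seg, diag, 2.0, FAST) == pytest.approx(5.0)


def test_spine_counted_once_even_if_near_two_segments(surface30):
    m = SpineMap.from_spines(surface30, [Spine(5.0, 15.0)])
    zigzag = ClimbPath(np.array([5.0, 6.0, 5.0]), np.array([0.0, 15.0, 30.0]))
    expected_len = 2 * np.hypot(1.0, 15.0)
    assert path_cost(m, zigzag, 4.0, FAST) == pytest.approx(expected_len + 10.0)


def test_invalid_paths_rejected(surface30, empty_map):
    with pytest.raises(InvalidPathError):
        ClimbPath(np.array([0.0, 1.0, 2.0]), np.array([0.0, 20.0, 10.0]))
    short = ClimbPath(np.array([0.0, 0.0]), np.array([0.0, 10.0]))
    with pytest.raises(InvalidPathError):
        path_cost(empty_map, short, 2.0, FAST)


def test_segments_take_short_way_around(surface30, empty_map):
    # from x=1 to x=29 the short way is 2 cm, not 28
    p = ClimbPath(np.array([1.0, 29.0]), np.array([0.0, 30.0]))
    assert path_cost(empty_map, p, 2.0, FAST) == pytest.approx(np.hypot(2.0, 30.0))


def test_empty_map_optimum_is_exact_height(empty_map):
    for k in (0, 1, 2):
        _, cost = best_path_at_level(empty_map, 3.0, k, FAST)
        assert cost == pytest.approx(30.0)
    res = optimize_climb(empty_map, 3.0, FAST)
    assert res.best_cost == pytest.approx(30.0)
    assert res.complexity_level == 0


def test_fence_forces_exactly_one_penalty(surface30):
    """Horizontal fence with 2-cm gaps, paw 2: every spanning path pays for at
    least one spine and an optimal one pays for exactly one."""
    xs = np.arange(0.0, 30.0, 2.0)
    fence = SpineMap(surface30, xs, np.full(xs.size, 15.0), np.zeros(xs.size))
    cfg = ClimbConfig(paths_per_level=5000, seed=2)
    res = optimize_climb(fence, 2.0, cfg)
    assert res.best_cost >= 40.0 - 1e-9
    assert res.best_cost <= 41.0


def test_dense_fence_lower_bound(surface30):
    xs = np.arange(0.0, 30.0, 0.5)
    fence = SpineMap(surface30, xs, np.full(xs.size, 15.0), np.zeros(xs.size))
    _, cost = best_path_at_level(fence, 2.0, 1, FAST)
    assert cost >= 30.0 + 10.0


def test_optimize_is_deterministic(presets, surface30):
    from spinedef.synth import generate_spine_map

    m = generate_spine_map(presets["crown"], surface30, seed=4)
    a = optimize_climb(m, 3.0, FAST)
    b = optimize_climb(m, 3.0, FAST)
    assert a.best_cost == b.best_cost
    np.testing.assert_array_equal(a.best_path.x, b.best_path.x)


def test_backends_agree(surface30):
    from spinedef.climb import _HAVE_NUMBA

    if not _HAVE_NUMBA:
        # single-backend build: the numpy path is the implementation
        return
    rng = np.random.default_rng(8)
    m = SpineMap(surface30, rng.uniform(0, 30, 50), rng.uniform(0, 30, 50),
                 np.zeros(50))
    X = rng.uniform(0, 30, size=(200, 3))
    Y = np.column_stack([np.zeros(200), rng.uniform(5, 25, 200), np.full(200, 30.0)])
    cfg = ClimbConfig()
    a = evaluate_path_costs(X, Y, m, 3.0, cfg, backend="numpy")
    b = evaluate_path_costs(X, Y, m, 3.0, cfg, backend="numba")
    np.testing.assert_allclose(a, b, rtol=1e-10)


def test_cost_lower_bound_and_paw_monotonicity(presets):
    from spinedef.synth import generate_spine_map

    m = generate_spine_map(presets["liana"], TrunkSurface(25.0, 30.0), seed=6)
    cfg = ClimbConfig(paw_sizes_cm=(1.0, 2.0, 4.0, 6.0), paths_per_level=2000,
                      seed=3)
    res = climb_sweep(m, cfg)
    costs = [r.best_cost for r in res]
    assert all(c >= 30.0 - 1e-9 for c in costs)
    assert all(a <= b + 1e-9 for a, b in zip(costs, costs[1:]))


def test_spine_addition_and_penalty_monotonicity():
    rng = np.random.default_rng(9)
    m = random_map(rng, max_spines=10, cmin=12.0, cmax=16.0)
    extra = [Spine(float(rng.uniform(0, m.surface.circumference_cm)),
                   float(rng.uniform(0, m.surface.height_cm)))
             for _ in range(6)]
    m2 = m.with_spines(extra)
    cfg = ClimbConfig(paths_per_level=3000, seed=5)
    assert optimize_climb(m2, 3.0, cfg).best_cost >= optimize_climb(m, 3.0, cfg).best_cost - 1e-9
    hi = ClimbConfig(paths_per_level=3000, seed=5, penalty=20.0)
    assert optimize_climb(m2, 3.0, hi).best_cost >= optimize_climb(m2, 3.0, cfg).best_cost - 1e-9


def test_shift_invariance_of_optimal_cost(presets):
    from spinedef.synth import generate_spine_map

    m = generate_spine_map(presets["crown"], TrunkSurface(24.0, 30.0), seed=7)
    cfg = ClimbConfig(paths_per_level=5000, seed=6)
    c1 = optimize_climb(m, 3.0, cfg).best_cost
    c2 = optimize_climb(m.translated(7.5), 3.0, cfg).best_cost
    assert c2 == pytest.approx(c1, rel=0.05)


def test_search_tracks_dp_optimum_on_toy_maps():
    rng = np.random.default_rng(10)
    cfg = ClimbConfig(paths_per_level=10_000, seed=11)
    for _ in range(6):
        m = random_map(rng, max_spines=8, cmin=8.0, cmax=15.0)
        paw = float(rng.integers(1, 5))
        dp = climb_dp_oracle(m, paw)
        mc = optimize_climb(m, paw, cfg).best_cost
        assert abs(mc - dp) <= 0.05 * dp
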