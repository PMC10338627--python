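import itertools
import math

import numpy as np
import pytest

from paccquant import (
    EndpointVector,
    MigrationSimConfig,
    TrajectorySet,
    build_report,
    classify_chemotaxis,
    compare_groups,
    compare_many,
    directness,
    forward_migration_indices,
    rayleigh_test,
    rayleigh_test_vector,
    simulate_trajectories,
)
from paccquant.chemotaxis import moore_null_statistics, moore_statistic
from paccquant.errors import ConfigurationError, InsufficientDataError

from conftest import make_trajectory


def _set(points_per_cell, gradient=(0.0, 1.0)):
    cells = tuple(
        make_trajectory(pts, cell_id=f"c{i}") for i, pts in enumerate(points_per_cell)
    )
    return TrajectorySet(trajectories=cells, gradient_axis=np.asarray(gradient))


# ---------------------------------------------------------------------------
# forward migration indices
# ---------------------------------------------------------------------------

def test_straight_up_gradient_cells_have_parallel_fmi_one():
    tset = _set([[(0, 0), (0, 5), (0, 10)] for _ in range(4)])
    fmi = forward_migration_indices(tset)
    assert fmi.fmi_parallel == pytest.approx(1.0)
    assert fmi.fmi_perpendicular == pytest.approx(0.0, abs=1e-12)


def test_straight_down_gradient_cells_have_parallel_fmi_minus_one():
    tset = _set([[(0, 0), (0, -7)] for _ in range(3)])
    assert forward_migration_indices(tset).fmi_parallel == pytest.approx(-1.0)


def test_fmi_components_tie_to_directness(random_cohort):
    fmi = forward_migration_indices(random_cohort)
    d = np.array([directness(t) for t in random_cohort])
    assert np.allclose(
        fmi.parallel_values**2 + fmi.perpendicular_values**2, d**2, atol=1e-9
    )


def test_fmi_requires_gradient_axis_and_skips_stationary_cells():
    no_axis = TrajectorySet(trajectories=(make_trajectory([(0, 0), (1, 1)]),))
    with pytest.raises(ConfigurationError):
        forward_migration_indices(no_axis)
    mixed = _set([[(0, 0), (0, 3)], [(1, 1), (1, 1)]])
    fmi = forward_migration_indices(mixed)
    assert fmi.n_missing == 1
    assert len(fmi.parallel_values) == 1


# ---------------------------------------------------------------------------
# Rayleigh test
# ---------------------------------------------------------------------------

def test_rayleigh_perfect_concentration():
    res = rayleigh_test(np.full(20, 0.7))
    assert res.mean_resultant_length == pytest.approx(1.0)
    assert res.z == pytest.approx(20.0)
    assert res.p < 1e-6


def test_rayleigh_compass_points_have_zero_resultant():
    res = rayleigh_test([0.0, math.pi / 2, math.pi, -math.pi / 2])
    assert res.mean_resultant_length == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0, abs=0.05)


def test_rayleigh_p_invariant_under_global_rotation(rng):
    angles = rng.uniform(-math.pi, math.pi, 40)
    base = rayleigh_test(angles)
    for shift in (0.3, 1.7, -2.9):
        rotated = np.angle(np.exp(1j * (angles + shift)))
        assert rayleigh_test(rotated).p == pytest.approx(base.p, rel=1e-9)


def test_rayleigh_needs_three_angles():
    with pytest.raises(InsufficientDataError):
        rayleigh_test([0.1, 0.2])


# ---------------------------------------------------------------------------
# Rayleigh test for vector data (Moore)
# ---------------------------------------------------------------------------

def test_vector_test_detects_common_direction_with_spread_magnitudes(rng):
    mags = rng.uniform(1, 30, 20)
    eps = [EndpointVector(0.0, m) for m in mags]  # all straight up
    res = rayleigh_test_vector(eps, seed=1)
    assert res.p < 0.01


def test_vector_test_flags_magnitude_ties():
    eps = [EndpointVector(math.cos(a), math.sin(a)) for a in np.linspace(-3, 3, 10)]
    res = rayleigh_test_vector(eps, seed=1)
    assert res.ties_in_magnitude  # all magnitudes equal → mid-ranks, noted


def test_vector_test_weights_dominant_magnitudes():
    """Magnitude-weighted sensitivity: when the largest endpoints share a
    direction, the rank-weighted test out-rejects the angle-only Rayleigh
    test in paired simulation."""
    rng = np.random.default_rng(5)
    null = moore_null_statistics(20, 20_000, np.random.default_rng(1))
    reps = 400
    rej_rayleigh = rej_moore = 0
    for _ in range(reps):
        angles = np.concatenate(
            [rng.uniform(-math.pi, math.pi, 16), rng.normal(math.pi / 2, 0.2, 4)]
        )
        mags = np.concatenate([rng.uniform(1, 5, 16), rng.uniform(40, 60, 4)])
        rej_rayleigh += rayleigh_test(angles).p < 0.05
        stat, _ = moore_statistic(angles, mags)
        p = (1 + np.count_nonzero(null >= stat)) / (null.size + 1)
        rej_moore += p < 0.05
    assert rej_moore > rej_rayleigh


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _reports_from(bias_by_label, n_cells=40, seed=0):
    reports = {}
    for i, (label, bias) in enumerate(bias_by_label.items()):
        cfg = MigrationSimConfig(
            n_cells=n_cells, drift_bias=bias, persistence=0.3, seed=seed + i
        )
        tset = simulate_trajectories(cfg, condition_label=label)
        reports[label] = build_report(tset, n_reps=4000, seed=seed + 50 + i)
    return reports


def test_gradient_identical_to_control_is_not_chemotaxis():
    cfg = MigrationSimConfig(n_cells=40, drift_bias=0.5, persistence=0.0, seed=13)
    tset = simulate_trajectories(cfg)
    report = build_report(tset, n_reps=2000, seed=1)
    reports = {
        "-/+": report,
        "+/+": report,  # same data: criterion i cannot pass
        "-/-": report,
    }
    result = classify_chemotaxis(reports)
    assert result.verdict is False
    assert not result.criteria["fmi_gradient_above_controls"]


def test_chemotactic_scenario_yields_true_with_full_criterion_trace():
    reports = _reports_from({"+/+": 0.0, "-/-": 0.0, "-/+": 0.5}, n_cells=60, seed=2)
    result = classify_chemotaxis(reports)
    assert result.verdict is True
    assert all(result.criteria.values())


def test_missing_condition_is_named_in_error():
    reports = _reports_from({"+/+": 0.0, "-/+": 0.5}, n_cells=20, seed=3)
    with pytest.raises(ConfigurationError, match=r"-/-"):
        classify_chemotaxis(reports)


def test_classifier_power_is_monotone_in_drift_bias():
    """Stronger gradient bias never reduces the detection rate (fixed seeds)."""
    rates = []
    for bias in (0.0, 0.25, 0.5):
        hits = 0
        reps = 10
        for r in range(reps):
            reports = _reports_from(
                {"+/+": 0.0, "-/-": 0.0, "-/+": bias}, n_cells=40, seed=1000 * r + 17
            )
            hits += classify_chemotaxis(reports).verdict
        rates.append(hits / reps)
    assert rates[0] <= rates[1] <= rates[2]


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def test_identical_groups_are_not_distinguishable():
    vals = [1.0, 2.0, 3.0, 4.0, 5.0]
    _, p = compare_groups(vals, vals)
    assert p >= 0.99


def test_fully_separated_groups_give_extreme_u_and_minimal_p():
    lo = list(range(10))
    hi = [v + 100 for v in lo]
    u, p = compare_groups(lo, hi)
    assert u in (0.0, 100.0)
    assert p < 1e-3


def test_small_sample_p_matches_exhaustive_permutation_enumeration():
    a = [1.2, 3.4, 0.5, 2.2]
    b = [2.9, 4.1, 3.8, 1.0]
    u_obs, p = compare_groups(a, b)
    pooled = np.array(a + b)
    n = len(a)

    def u_of(idx_a):
        xa = pooled[list(idx_a)]
        xb = np.delete(pooled, list(idx_a))
        gt = sum((x > y) + 0.5 * (x == y) for x in xa for y in xb)
        return gt

    us = [u_of(c) for c in itertools.combinations(range(8), n)]
    u_a = u_of(range(n))
    # two-sided: as extreme in either tail
    mean_u = len(a) * len(b) / 2
    p_exact = np.mean([abs(u - mean_u) >= abs(u_a - mean_u) - 1e-12 for u in us])
    assert p == pytest.approx(p_exact, abs=1e-9)


def test_compare_many_flags_separated_groups_and_validates_input():
    h, p = compare_many([[1, 2, 3, 4], [10, 11, 12, 13], [20, 21, 22, 23]])
    assert p < 0.05
    with pytest.raises(InsufficientDataError):
        compare_many([[1, 2, 3]])
    with pytest.raises(InsufficientDataError):
        compare_groups([], [1, 2])
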