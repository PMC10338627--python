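import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import truncnorm

from paccquant import (
    BeadSimConfig,
    HertzSimConfig,
    MigrationSimConfig,
    accumulated_distance,
    compute_msd,
    directness,
    euclidean_distance,
    fit_msd_exponent,
    forward_migration_indices,
    simulate_bead_tracks,
    simulate_ct_table,
    simulate_force_curve,
    simulate_trajectories,
)
from paccquant.errors import ConfigurationError, DegenerateParameterError
from paccquant.expression import delta_delta_ct
from paccquant.synthetic import vonmises_kappa_from_resultant


# ---------------------------------------------------------------------------
# migration walks
# ---------------------------------------------------------------------------

def test_identical_seed_and_config_give_bitwise_identical_trajectories():
    cfg = MigrationSimConfig(n_cells=10, drift_bias=0.3, persistence=0.5, seed=42)
    a = simulate_trajectories(cfg)
    b = simulate_trajectories(cfg)
    for ta, tb in zip(a, b):
        assert np.array_equal(ta.xy, tb.xy)
        assert np.array_equal(ta.times, tb.times)


def test_growing_the_cohort_never_reshuffles_earlier_cells():
    small = simulate_trajectories(MigrationSimConfig(n_cells=5, drift_bias=0.2, seed=7))
    big = simulate_trajectories(MigrationSimConfig(n_cells=12, drift_bias=0.2, seed=7))
    for ts, tb in zip(small, big):
        assert np.array_equal(ts.xy, tb.xy)


def test_fully_biased_noiseless_walk_is_a_straight_gradient_line():
    cfg = MigrationSimConfig(
        n_cells=5, drift_bias=1.0, persistence=0.0, step_speed_sd=0.0,
        gradient_axis=(1.0, 0.0), seed=3,
    )
    tset = simulate_trajectories(cfg)
    for t in tset:
        assert directness(t) == pytest.approx(1.0)
        assert np.allclose(t.xy[:, 1], 0.0)           # no motion off-axis
        assert np.all(np.diff(t.xy[:, 0]) > 0)        # monotone up the gradient


def test_unbiased_walk_has_zero_mean_fmi_within_three_se():
    cfg = MigrationSimConfig(n_cells=500, drift_bias=0.0, persistence=0.0, seed=11)
    fmi = forward_migration_indices(simulate_trajectories(cfg))
    for vals in (fmi.parallel_values, fmi.perpendicular_values):
        se = vals.std(ddof=1) / math.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * se


def test_unbiased_walk_mean_endpoint_within_three_se_of_origin():
    """Cohorts of 1000 unbiased walkers drift to the origin on average.

    Any single 3-SE assertion has a ~1% false-alarm rate, so the check is
    made on a block of independent cohorts: the pooled mean must sit
    within 3 SE and at most one individual cohort may stray outside.
    """
    cohorts = []
    for seed in range(5):
        cfg = MigrationSimConfig(n_cells=1000, drift_bias=0.0, persistence=0.3, seed=seed)
        cohorts.append(
            np.array([t.xy[-1] - t.xy[0] for t in simulate_trajectories(cfg)])
        )
    pooled = np.concatenate(cohorts)
    outside = 0
    for ends in cohorts:
        se = ends.std(axis=0, ddof=1) / math.sqrt(len(ends))
        outside += bool(np.any(np.abs(ends.mean(axis=0)) > 3 * se))
    assert outside <= 1
    pooled_se = pooled.std(axis=0, ddof=1) / math.sqrt(len(pooled))
    assert np.all(np.abs(pooled.mean(axis=0)) < 3 * pooled_se)


def test_generator_output_respects_triangle_inequality():
    cfg = MigrationSimConfig(n_cells=100, drift_bias=0.5, persistence=0.6, seed=5)
    for t in simulate_trajectories(cfg):
        assert euclidean_distance(t) <= accumulated_distance(t) + 1e-9


def _reference_walk(config: MigrationSimConfig) -> list:
    """Independent straightforward re-implementation of the update rule."""
    g = np.asarray(config.gradient_axis, float)
    g = g / np.hypot(*g)
    n_steps = config.n_frames - 1
    mean = config.step_speed_mean * config.frame_interval
    sd = config.step_speed_sd * config.frame_interval
    paths = []
    for child in np.random.SeedSequence(config.seed).spawn(config.n_cells):
        rng = np.random.default_rng(child)
        if sd == 0:
            lengths = np.full(n_steps, mean)
        else:
            lengths = truncnorm.rvs(-mean / sd, np.inf, loc=mean, scale=sd,
                                    size=n_steps, random_state=rng)
        pos = [np.zeros(2)]
        heading = None
        for k in range(n_steps):
            v = config.drift_bias * g + (config.persistence * heading if heading is not None else 0.0)
            c = float(np.linalg.norm(v))
            if c >= 1.0:
                theta = math.atan2(v[1], v[0])
            elif c == 0.0:
                theta = rng.uniform(-math.pi, math.pi)
            else:
                theta = math.atan2(v[1], v[0]) + float(
                    rng.vonmises(0.0, vonmises_kappa_from_resultant(c))
                )
            heading = np.array([math.cos(theta), math.sin(theta)])
            pos.append(pos[-1] + lengths[k] * heading)
        paths.append(np.array(pos))
    return paths


def test_walk_matches_independent_reimplementation_exactly():
    cfg = MigrationSimConfig(n_cells=200, drift_bias=0.5, persistence=0.0, seed=7)
    tset = simulate_trajectories(cfg)
    reference = _reference_walk(cfg)
    for t, ref in zip(tset, reference):
        assert np.array_equal(t.xy, ref)
    # downstream FMI therefore matches a same-seed re-run exactly
    again = forward_migration_indices(simulate_trajectories(cfg))
    first = forward_migration_indices(tset)
    assert first.fmi_parallel == again.fmi_parallel


@pytest.mark.parametrize(
    "kwargs, field",
    [
        (dict(n_cells=0), "n_cells"),
        (dict(n_cells=5, n_frames=1), "n_frames"),
        (dict(n_cells=5, frame_interval=0.0), "frame_interval"),
        (dict(n_cells=5, persistence=1.0), "persistence"),
        (dict(n_cells=5, drift_bias=1.5), "drift_bias"),
        (dict(n_cells=5, gradient_axis=(0.0, 0.0)), "gradient_axis"),
    ],
)
def test_invalid_migration_config_names_offending_field(kwargs, field):
    with pytest.raises(ConfigurationError, match=field):
        MigrationSimConfig(**kwargs)


# ---------------------------------------------------------------------------
# bead tracks
# ---------------------------------------------------------------------------

def test_zero_diffusion_gives_constant_positions_and_zero_msd():
    cfg = BeadSimConfig(n_beads=5, duration=5, diffusion_coefficient=0.0, seed=1)
    tracks = simulate_bead_tracks(cfg)
    for track in tracks:
        assert np.array_equal(track.xy, np.zeros_like(track.xy))
    curve = compute_msd(tracks, max_lag=2.0)
    assert np.allclose(curve.msd, 0.0)


def test_brownian_msd_at_one_second_matches_4dt_analytic():
    cfg = BeadSimConfig(n_beads=1000, duration=10, diffusion_coefficient=2500.0, seed=2)
    curve = compute_msd(simulate_bead_tracks(cfg), max_lag=1.0)
    msd_1s = curve.msd[np.argmin(np.abs(curve.lags - 1.0))]
    assert msd_1s == pytest.approx(4 * 2500.0 * 1.0, rel=0.05)


def test_subdiffusive_exponent_recovered_by_loglog_regression():
    cfg = BeadSimConfig(
        n_beads=200, duration=30, diffusion_coefficient=2500.0,
        anomalous_exponent=0.5, seed=3,
    )
    curve = compute_msd(simulate_bead_tracks(cfg), max_lag=3.0)
    slope = fit_msd_exponent(curve)
    assert slope == pytest.approx(0.5, abs=0.08)
    # amplitude also matches the generator's closed form MSD(τ) = 4·D·τ^a
    msd_1s = curve.msd[np.argmin(np.abs(curve.lags - 1.0))]
    assert msd_1s == pytest.approx(4 * 2500.0, rel=0.15)


def test_bead_generator_is_deterministic():
    cfg = BeadSimConfig(n_beads=3, duration=5, diffusion_coefficient=100.0, seed=9)
    a = simulate_bead_tracks(cfg)
    b = simulate_bead_tracks(cfg)
    for ta, tb in zip(a, b):
        assert np.array_equal(ta.xy, tb.xy)


def test_negative_diffusion_rejected():
    with pytest.raises(ConfigurationError, match="diffusion_coefficient"):
        BeadSimConfig(diffusion_coefficient=-1.0)


# ---------------------------------------------------------------------------
# force curves
# ---------------------------------------------------------------------------

def test_noiseless_force_curve_matches_hertz_equation_at_full_indentation():
    cfg = HertzSimConfig(youngs_modulus_true=1000.0, max_indentation=1e-6, n_points=100)
    curve = simulate_force_curve(cfg)
    # F = 2·E·tanα/(π(1−ν²))·δ² at δ = 1 µm, E = 1 kPa, α = 35°, ν = 0.5
    expected = 2 * 1000.0 * math.tan(math.radians(35.0)) / (math.pi * 0.75) * (1e-6) ** 2
    assert expected == pytest.approx(5.94e-10, rel=1e-3)
    assert curve.force[-1] == pytest.approx(expected, rel=1e-12)


def test_zero_modulus_gives_identically_zero_force():
    curve = simulate_force_curve(HertzSimConfig(youngs_modulus_true=0.0))
    assert np.allclose(curve.force, 0.0)


def test_same_seed_gives_identical_noise_realization():
    cfg = HertzSimConfig(youngs_modulus_true=500.0, force_noise_sd=1e-11, seed=4)
    assert np.array_equal(simulate_force_curve(cfg).force, simulate_force_curve(cfg).force)


def test_poisson_ratio_one_is_degenerate():
    with pytest.raises(DegenerateParameterError):
        HertzSimConfig(youngs_modulus_true=1000.0, poisson_ratio=1.0)


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

def test_noiseless_ct_tables_encode_the_exact_fold_change():
    unit = delta_delta_ct(simulate_ct_table(1.0, n_replicates=3))
    assert unit.mean_ddct == pytest.approx(0.0)
    assert unit.fold_change_summary == pytest.approx(1.0)
    sixteen = delta_delta_ct(simulate_ct_table(16.0, n_replicates=3))
    assert sixteen.mean_ddct == pytest.approx(-4.0)
    assert np.allclose(sixteen.fold_change, 16.0)


def test_noisy_ct_recovery_covers_truth():
    folds = []
    for seed in range(30):
        res = delta_delta_ct(simulate_ct_table(3.5, n_replicates=6, ct_noise_sd=0.2, seed=seed))
        folds.append(res.fold_change_summary)
    folds = np.asarray(folds)
    ci = 1.96 * folds.std(ddof=1) / math.sqrt(folds.size)
    assert abs(folds.mean() - 3.5) < ci + 0.1


def test_nonpositive_fold_change_rejected():
    with pytest.raises(ConfigurationError, match="fold_change_true"):
        simulate_ct_table(0.0, n_replicates=3)
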