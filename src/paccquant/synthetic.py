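"""Synthetic data with known ground truth for every assay in the package.

The generators emulate the acquisition geometry of the real experiments —
24-h time-lapse trajectories sampled every 30 min, Brownian bead tracks at
12 frames/s for ~300 s with ~100 beads per field, conical-tip Hertzian
force curves, and qPCR Ct tables — while every "biological" parameter
(speed, persistence, gradient bias, diffusion coefficient, modulus, fold
change) is an explicit, recoverable truth.  That makes each downstream
estimator testable as a parameter-recovery problem.

Migration model
---------------
Cells perform a biased persistent random walk.  At each frame the step
direction is drawn from a von Mises distribution whose mean is the
direction of the resultant vector

    v = persistence · ĥ  +  drift_bias · ĝ

(ĥ previous heading, ĝ gradient axis) and whose concentration κ is chosen
so that the mean resultant length of the von Mises noise equals ‖v‖
(Best–Fisher inversion).  Consequences that anchor the two knobs:

* ``drift_bias = 0`` and no history → ‖v‖ = 0 → uniform direction
  (isotropic walk, zero expected FMI);
* ``‖v‖ ≥ 1`` (e.g. drift_bias = 1, persistence = 0) → a deterministic
  step along v (perfectly straight chemotaxis, directness 1);
* with drift_bias = 0, ``persistence`` is (approximately) the circular
  correlation of successive step directions.

Step lengths are truncated-normal: speed ~ N(mean, sd) · frame_interval,
truncated at zero.  Each cell consumes its own child RNG stream spawned
from the master seed, so enlarging ``n_cells`` never reshuffles earlier
cells and every generator is a pure function of (config, seed).

Bead model
----------
Independent 2D Gaussian-increment motion.  For ``anomalous_exponent`` a=1
this is Brownian motion with per-axis increment variance 2·D·Δt, so the
ensemble MSD at lag t is 4·D·t (nm²).  For a ≠ 1 increments are exact
fractional Gaussian noise with Hurst index H = a/2 synthesised by
circulant embedding (Davies–Harte), giving stationary increments with
MSD(τ) = 4·D·τ^a.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .biomechanics import BeadTrack, BeadTrackSet, ForceCurve, hertz_prefactor
from .errors import ConfigurationError
from .trajectories import Trajectory, TrajectorySet

__all__ = [
    "MigrationSimConfig",
    "simulate_trajectories",
    "BeadSimConfig",
    "simulate_bead_tracks",
    "HertzSimConfig",
    "simulate_force_curve",
    "simulate_ct_table",
    "vonmises_kappa_from_resultant",
]


def _check(condition: bool, fieldname: str, message: str) -> None:
    if not condition:
        raise ConfigurationError(f"{fieldname}: {message}")


# ---------------------------------------------------------------------------
# Migration trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MigrationSimConfig:
    """Ground-truth parameters of the biased persistent random walk.

    Defaults reproduce the acquisition cadence of the time-lapse assay
    (49 frames at 30-min intervals = 24 h).  Speeds are deliberately
    arbitrary, documented defaults — the real per-cell speeds were never
    published — chosen at a scale typical of slow epithelial migration.
    """

    n_cells: int
    n_frames: int = 49
    frame_interval: float = 30.0          # minutes
    step_speed_mean: float = 0.5          # µm/min
    step_speed_sd: float = 0.2            # µm/min
    persistence: float = 0.0              # in [0, 1): heading correlation
    drift_bias: float = 0.0               # in [0, 1]: pull toward gradient
    gradient_axis: tuple = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        _check(self.n_cells >= 1, "n_cells", "must be ≥ 1")
        _check(self.n_frames >= 2, "n_frames", "must be ≥ 2")
        _check(self.frame_interval > 0, "frame_interval", "must be > 0")
        _check(self.step_speed_mean >= 0, "step_speed_mean", "must be ≥ 0")
        _check(self.step_speed_sd >= 0, "step_speed_sd", "must be ≥ 0")
        _check(0.0 <= self.persistence < 1.0, "persistence", "must be in [0, 1)")
        _check(0.0 <= self.drift_bias <= 1.0, "drift_bias", "must be in [0, 1]")
        g = np.asarray(self.gradient_axis, dtype=float)
        _check(g.shape == (2,) and np.hypot(*g) > 0, "gradient_axis", "must be a nonzero 2-vector")


def vonmises_kappa_from_resultant(rbar: float) -> float:
    """κ such that a von Mises sample has mean resultant length ≈ rbar.

    Best–Fisher piecewise approximation of the inverse of A(κ)=I₁(κ)/I₀(κ);
    standard in circular statistics and accurate to ~1e-3 over (0, 1).
    """
    r = float(rbar)
    if r <= 0.0:
        return 0.0
    if r < 0.53:
        return 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    return 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)


def _step_lengths(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    if sd == 0.0:
        return np.full(n, mean)
    a = (0.0 - mean) / sd  # truncate at zero
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def _walk_one_cell(
    rng: np.random.Generator,
    n_steps: int,
    step_mean_um: float,
    step_sd_um: float,
    persistence: float,
    drift_bias: float,
    g: np.ndarray,
) -> np.ndarray:
    lengths = _step_lengths(rng, n_steps, step_mean_um, step_sd_um)
    xy = np.zeros((n_steps + 1, 2))
    heading = None
    for t in range(n_steps):
        v = drift_bias * g
        if heading is not None:
            v = v + persistence * heading
        c = float(np.hypot(v[0], v[1]))
        if c >= 1.0:
            theta = math.atan2(v[1], v[0])
        elif c == 0.0:
            theta = rng.uniform(-math.pi, math.pi)
        else:
            mu = math.atan2(v[1], v[0])
            theta = mu + float(rng.vonmises(0.0, vonmises_kappa_from_resultant(c)))
        heading = np.array([math.cos(theta), math.sin(theta)])
        xy[t + 1] = xy[t] + lengths[t] * heading
    return xy


def simulate_trajectories(
    config: MigrationSimConfig, condition_label: str = "-/+"
) -> TrajectorySet:
    """Simulate a cohort of biased persistent random walks.

    Returns a :class:`TrajectorySet` carrying the (normalised) gradient
    axis; positions in µm, times in minutes, no exclusion flags.
    Bitwise reproducible for a fixed config.
    """
    g = np.asarray(config.gradient_axis, dtype=float)
    g = g / np.hypot(*g)
    n_steps = config.n_frames - 1
    times = config.frame_interval * np.arange(config.n_frames)
    step_mean = config.step_speed_mean * config.frame_interval
    step_sd = config.step_speed_sd * config.frame_interval
    children = np.random.SeedSequence(config.seed).spawn(config.n_cells)
    trajectories = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        xy = _walk_one_cell(
            rng, n_steps, step_mean, step_sd, config.persistence, config.drift_bias, g
        )
        trajectories.append(Trajectory(cell_id=f"cell{i:04d}", times=times, xy=xy))
    return TrajectorySet(
        trajectories=tuple(trajectories),
        condition_label=condition_label,
        gradient_axis=g,
    )


# ---------------------------------------------------------------------------
# Bead tracks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadSimConfig:
    """Ground truth for spontaneous bead motion (nm, seconds).

    Defaults mirror the video-microscopy acquisition: ~100 beads per
    field recorded at 12 frames/s for ~300 s.
    """

    n_beads: int = 100
    duration: float = 300.0               # seconds
    frame_rate: float = 12.0              # frames/s
    diffusion_coefficient: float = 100.0  # nm²/s
    anomalous_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self):
        _check(self.n_beads >= 1, "n_beads", "must be ≥ 1")
        _check(self.duration * self.frame_rate >= 2, "duration",
               "duration·frame_rate must give ≥ 2 samples")
        _check(self.diffusion_coefficient >= 0, "diffusion_coefficient", "must be ≥ 0")
        _check(0.0 < self.anomalous_exponent <= 2.0, "anomalous_exponent", "must be in (0, 2]")


def _fgn(n: int, hurst: float, rng: np.random.Generator, n_series: int) -> np.ndarray:
    """(n_series, n) unit-variance fractional Gaussian noise, Davies–Harte.

    Circulant embedding of the fGn autocovariance; each complex spectral
    draw yields two independent real series (real and imaginary parts),
    so series are generated in pairs.
    """
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([gamma, gamma[-2:0:-1]])   # length 2n
    lam = np.fft.fft(row).real
    lam = np.where(lam < 0, 0.0, lam)               # guard tiny negative eigenvalues
    m = row.size
    pairs = (n_series + 1) // 2
    xi = (rng.standard_normal((pairs, m)) + 1j * rng.standard_normal((pairs, m))) / math.sqrt(2)
    y = np.fft.fft(np.sqrt(lam) * xi, axis=1) / math.sqrt(m)
    out = np.empty((2 * pairs, n))
    out[0::2] = math.sqrt(2) * y.real[:, :n]
    out[1::2] = math.sqrt(2) * y.imag[:, :n]
    return out[:n_series]


def simulate_bead_tracks(config: BeadSimConfig) -> BeadTrackSet:
    """Simulate spontaneous 2D bead motion with known D (and exponent a).

    For a = 1 increments are iid Gaussian with per-axis variance 2·D·Δt
    (ensemble MSD(τ) = 4·D·τ).  For a ≠ 1 increments are exact fGn with
    H = a/2 scaled so MSD(τ) = 4·D·τ^a.
    """
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.frame_rate
    n_samples = int(round(config.duration * config.frame_rate)) + 1
    n_steps = n_samples - 1
    d = config.diffusion_coefficient
    times = dt * np.arange(n_samples)
    if d == 0.0:
        increments = np.zeros((config.n_beads, 2, n_steps))
    elif config.anomalous_exponent == 1.0:
        sd = math.sqrt(2.0 * d * dt)
        increments = sd * rng.standard_normal((config.n_beads, 2, n_steps))
    else:
        h = config.anomalous_exponent / 2.0
        scale = math.sqrt(2.0 * d) * dt**h
        flat = _fgn(n_steps, h, rng, 2 * config.n_beads)
        increments = scale * flat.reshape(config.n_beads, 2, n_steps)
    paths = np.concatenate(
        [np.zeros((config.n_beads, 2, 1)), np.cumsum(increments, axis=2)], axis=2
    )
    tracks = tuple(
        BeadTrack(bead_id=f"bead{i:04d}", times=times, xy=paths[i].T)
        for i in range(config.n_beads)
    )
    return BeadTrackSet(tracks=tracks, frame_rate=config.frame_rate)


# ---------------------------------------------------------------------------
# AFM force curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HertzSimConfig:
    """Ground truth for a conical-tip Hertzian indentation curve (SI units)."""

    youngs_modulus_true: float            # Pa
    tip_half_angle: float = 35.0          # degrees
    poisson_ratio: float = 0.5
    max_indentation: float = 1e-6         # meters
    n_points: int = 200
    force_noise_sd: float = 0.0           # Newtons
    seed: int = 0

    def __post_init__(self):
        _check(self.youngs_modulus_true >= 0, "youngs_modulus_true", "must be ≥ 0")
        _check(self.max_indentation > 0, "max_indentation", "must be > 0")
        _check(self.n_points >= 2, "n_points", "must be ≥ 2")
        _check(self.force_noise_sd >= 0, "force_noise_sd", "must be ≥ 0")
        # hertz_prefactor raises DegenerateParameterError for ν ∉ (0,1), α ∉ (0,90)
        hertz_prefactor(self.tip_half_angle, self.poisson_ratio)


def simulate_force_curve(config: HertzSimConfig) -> ForceCurve:
    """F = [2·E·tanα/(π(1−ν²))]·δ² plus optional Gaussian force noise.

    δ spans [0, max_indentation] on a uniform grid; identical seed and
    config give an identical noise realisation.
    """
    delta = np.linspace(0.0, config.max_indentation, config.n_points)
    k = hertz_prefactor(config.tip_half_angle, config.poisson_ratio)
    force = k * config.youngs_modulus_true * delta**2
    if config.force_noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        force = force + rng.normal(0.0, config.force_noise_sd, size=delta.size)
    return ForceCurve(
        indentation=delta,
        force=force,
        tip_half_angle=config.tip_half_angle,
        poisson_ratio=config.poisson_ratio,
    )


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

#: Baseline cycle thresholds used by the Ct generator: the housekeeping
#: gene amplifies early (abundant transcript); the target sits a few
#: cycles later in the control condition.
_CT_HOUSEKEEPING = 18.0
_CT_TARGET_CONTROL_OFFSET = 4.0


def simulate_ct_table(
    fold_change_true: float,
    n_replicates: int,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table (one row per replicate) with a known expression fold change.

    Columns: ``ct_target_treated``, ``ct_housekeeping_treated``,
    ``ct_target_control``, ``ct_housekeeping_control`` (cycles).  In the
    noiseless table ΔΔCt = −log₂(fold_change_true) exactly, so the
    delta-delta Ct estimator returns ``fold_change_true``.  Gaussian
    noise of sd ``ct_noise_sd`` cycles is added independently to each Ct.
    """
    if not fold_change_true > 0:
        raise ConfigurationError(f"fold_change_true: must be > 0, got {fold_change_true}")
    if n_replicates < 1:
        raise ConfigurationError("n_replicates: must be ≥ 1")
    if ct_noise_sd < 0:
        raise ConfigurationError("ct_noise_sd: must be ≥ 0")
    rng = np.random.default_rng(seed)
    hk = _CT_HOUSEKEEPING
    target_control = hk + _CT_TARGET_CONTROL_OFFSET
    target_treated = target_control - math.log2(fold_change_true)
    base = np.array([target_treated, hk, target_control, hk])
    table = np.tile(base, (n_replicates, 1))
    if ct_noise_sd > 0:
        table = table + rng.normal(0.0, ct_noise_sd, size=table.shape)
    return pd.DataFrame(
        table,
        columns=[
            "ct_target_treated",
            "ct_housekeeping_treated",
            "ct_target_control",
            "ct_housekeeping_control",
        ],
    )
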