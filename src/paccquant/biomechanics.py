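"""Cytoskeletal dynamics and stiffness estimators.

Three assays share this module:

* **Bead MSD** — cytoskeleton-anchored microbeads are tracked at video
  rate; the mean squared displacement MSD(τ) (nm²) over lag time reports
  cytoskeletal remodelling dynamics.  The estimator averages over all
  overlapping start times within a bead and then over the bead ensemble.
* **Magnetic twisting cytometry (MTC)** — a sinusoidal specific torque
  (Pa) twists the beads; cell stiffness is the ratio of torque amplitude
  to lateral bead displacement amplitude (Pa/nm), both extracted at the
  driving frequency by least-squares sinusoid fits, so an arbitrary phase
  lag between the two signals does not matter.
* **AFM indentation** — for a conical tip of half-opening angle α on an
  incompressible soft sample (Poisson ratio ν), the Hertz contact model
  relates force to indentation as

      F = [2·E·tan α / (π·(1 − ν²))] · δ²

  The Young's modulus E is the single linear coefficient once δ² is the
  regressor, so the fit is solved in closed form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DataError,
    DegenerateParameterError,
    InsufficientDataError,
    UnmeasurableSignalError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Bead tracks and MSD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadTrack:
    """One bead's positions over time: seconds and nm, uniformly sampled."""

    bead_id: str
    times: np.ndarray
    xy: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        xy = np.asarray(self.xy, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "xy", xy)
        if times.ndim != 1 or xy.shape != (times.size, 2):
            raise DataError(f"bead {self.bead_id!r}: times/xy must be (n,) and (n, 2)")
        if times.size >= 2:
            dt = np.diff(times)
            if not np.all(dt > 0):
                raise DataError(f"bead {self.bead_id!r}: times must be strictly increasing")
            if np.ptp(dt) > 1e-6 * dt[0]:
                raise DataError(f"bead {self.bead_id!r}: sampling must be uniform")

    @property
    def n_samples(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class BeadTrackSet:
    tracks: tuple
    frame_rate: float  # frames per second

    def __post_init__(self):
        object.__setattr__(self, "tracks", tuple(self.tracks))
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be > 0")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)


@dataclass(frozen=True)
class MsdCurve:
    """Ensemble- and time-averaged MSD per lag; msd(0)=0 by convention."""

    lags: np.ndarray        # seconds, strictly increasing, starts after 0
    msd: np.ndarray         # nm²
    n_pairs_per_lag: np.ndarray


def compute_msd(trackset: BeadTrackSet, max_lag: float) -> MsdCurve:
    """MSD(τ) averaged over overlapping start times and the bead ensemble.

    For each lag τ = k·Δt up to ``max_lag`` (seconds), averages
    |r(t+τ) − r(t)|² over every overlapping pair within every bead.  The
    number of contributing pairs per lag is recorded.
    """
    usable = [t for t in trackset if t.n_samples >= 2]
    if not usable:
        raise InsufficientDataError("MSD needs ≥ 1 track with ≥ 2 samples")
    dt = 1.0 / trackset.frame_rate
    longest = max(t.n_samples for t in usable)
    max_k = int(np.floor(max_lag / dt + 1e-9))
    if max_k < 1 or max_k > longest - 1:
        raise DataError(
            f"max_lag={max_lag} s out of bounds for tracks of ≤ {(longest - 1) * dt:.6g} s"
        )
    sums = np.zeros(max_k)
    counts = np.zeros(max_k, dtype=np.int64)
    for track in usable:
        pos = track.xy
        n = pos.shape[0]
        for k in range(1, min(max_k, n - 1) + 1):
            d = pos[k:] - pos[:-k]
            sums[k - 1] += float(np.einsum("ij,ij->", d, d))
            counts[k - 1] += n - k
    valid = counts > 0
    lags = dt * np.arange(1, max_k + 1)
    msd = np.full(max_k, np.nan)
    msd[valid] = sums[valid] / counts[valid]
    return MsdCurve(lags=lags[valid], msd=msd[valid], n_pairs_per_lag=counts[valid])


def fit_diffusion_coefficient(curve: MsdCurve) -> tuple[float, float]:
    """Diffusion coefficient from a linear MSD fit: slope/4 (nm²/s), with R².

    For 2D Brownian motion MSD(τ) = 4·D·τ; an intercept is retained to
    absorb localisation noise.
    """
    if curve.lags.size < 2:
        raise InsufficientDataError("need ≥ 2 lags to fit a line")
    coeffs, res = np.polyfit(curve.lags, curve.msd, 1), None
    pred = np.polyval(coeffs, curve.lags)
    ss_res = float(np.sum((curve.msd - pred) ** 2))
    ss_tot = float(np.sum((curve.msd - curve.msd.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(coeffs[0]) / 4.0, r2


def fit_msd_exponent(curve: MsdCurve) -> float:
    """Anomalous-diffusion exponent: slope of log MSD vs log lag."""
    mask = (curve.msd > 0) & (curve.lags > 0)
    if np.count_nonzero(mask) < 2:
        raise InsufficientDataError("need ≥ 2 positive MSD values for a log–log fit")
    slope, _ = np.polyfit(np.log(curve.lags[mask]), np.log(curve.msd[mask]), 1)
    return float(slope)


# ---------------------------------------------------------------------------
# AFM force curves and the Hertz fit
# ---------------------------------------------------------------------------

def hertz_prefactor(tip_half_angle_deg: float, poisson_ratio: float) -> float:
    """2·tan(α)/(π·(1−ν²)) — the geometry factor of the conical Hertz model.

    α is stored in degrees as instruments print it and converted here.
    """
    if not 0.0 < tip_half_angle_deg < 90.0:
        raise ConfigurationError(
            f"tip_half_angle must be in (0, 90) degrees, got {tip_half_angle_deg}"
        )
    if not 0.0 < poisson_ratio < 1.0:
        raise DegenerateParameterError(
            f"poisson_ratio must be in (0, 1) strictly, got {poisson_ratio}"
        )
    alpha = math.radians(tip_half_angle_deg)
    return 2.0 * math.tan(alpha) / (math.pi * (1.0 - poisson_ratio**2))


@dataclass(frozen=True)
class ForceCurve:
    """AFM force–indentation samples in SI units (m, N).

    ``tip_half_angle`` in degrees; ``poisson_ratio`` dimensionless
    (0.5 for incompressible soft biological material).
    """

    indentation: np.ndarray
    force: np.ndarray
    tip_half_angle: float = 35.0
    poisson_ratio: float = 0.5

    def __post_init__(self):
        d = np.asarray(self.indentation, dtype=float)
        f = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "indentation", d)
        object.__setattr__(self, "force", f)
        if d.ndim != 1 or d.shape != f.shape:
            raise DataError("indentation and force must be equal-length 1D arrays")
        if np.any(d < 0):
            raise DataError("indentation must be nonnegative")
        hertz_prefactor(self.tip_half_angle, self.poisson_ratio)  # validates α, ν


@dataclass(frozen=True)
class HertzFit:
    youngs_modulus: float  # Pa
    residual_rms: float    # N
    n_points: int
    clamped: bool = False


def fit_hertz(curve: ForceCurve, max_indentation: float | None = None) -> HertzFit:
    """Least-squares Young's modulus from F = k(α, ν)·E·δ².

    With the geometry prefactor k known, E is linear in the regressor δ²
    and the optimum is closed-form: Ê = Σ F·δ² / (k·Σ δ⁴).  Points with
    δ = 0 carry no information and points beyond ``max_indentation``
    (e.g. past the instrument's force setpoint) are excluded.  A negative
    estimate (possible under heavy noise) is clamped to 0 with a warning.
    """
    d = curve.indentation
    f = curve.force
    if max_indentation is not None:
        keep = d <= max_indentation
        d, f = d[keep], f[keep]
    positive = d > 0
    if np.count_nonzero(positive) < 1 or d.size < 1:
        raise DataError("Hertz fit needs at least one point with δ > 0")
    if np.count_nonzero(positive) < 3:
        logger.warning("Hertz fit on < 3 positive-indentation points; estimate is fragile")
    d, f = d[positive], f[positive]
    k = hertz_prefactor(curve.tip_half_angle, curve.poisson_ratio)
    d2 = d * d
    e_hat = float(np.dot(f, d2) / (k * np.dot(d2, d2)))
    clamped = False
    if e_hat < 0.0:
        logger.warning("Hertz fit produced E = %.3g Pa < 0; clamping to 0", e_hat)
        e_hat, clamped = 0.0, True
    resid = f - k * e_hat * d2
    return HertzFit(
        youngs_modulus=e_hat,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=int(d.size),
        clamped=clamped,
    )


@dataclass(frozen=True)
class ContactPointResult:
    offset: float          # piezo position of tip-sample contact (m)
    contact_index: int
    baseline: float        # pre-contact force offset (N)
    excluded: bool         # True when no contact is detectable
    sse: float


def estimate_contact_point(
    position: Sequence[float],
    force: Sequence[float],
    min_baseline_points: int = 5,
    snr_threshold: float = 3.0,
) -> ContactPointResult:
    """Locate tip–sample contact on a raw approach curve.

    Fits, for every candidate contact position z₀, the piecewise model

        F(z) = b                      for z < z₀   (free cantilever)
        F(z) = b + c·(z − z₀)²        for z ≥ z₀   (Hertzian rise, c ≥ 0)

    and keeps the z₀ with the smallest total squared error.  Indentation
    should then be recomputed as δ = z − z₀ for z ≥ z₀.  When the fitted
    rise above baseline at full approach is below ``snr_threshold`` times
    the baseline residual scatter the curve is flagged ``excluded``
    (no detectable contact), not an error.
    """
    z = np.asarray(position, dtype=float)
    f = np.asarray(force, dtype=float)
    if z.ndim != 1 or z.shape != f.shape or z.size < 2 * min_baseline_points:
        raise DataError("contact-point estimate needs a 1D monotone approach segment")
    if not np.all(np.diff(z) > 0):
        raise DataError("approach positions must be strictly increasing")

    best = None
    for i in range(min_baseline_points, z.size - min_baseline_points):
        b = float(f[:i].mean())
        dz2 = (z[i:] - z[i]) ** 2
        denom = float(np.dot(dz2, dz2))
        c = max(0.0, float(np.dot(f[i:] - b, dz2) / denom)) if denom > 0 else 0.0
        sse = float(np.sum((f[:i] - b) ** 2)) + float(np.sum((f[i:] - b - c * dz2) ** 2))
        if best is None or sse < best[0]:
            best = (sse, i, b, c)
    sse, idx, baseline, c = best
    rise = c * (z[-1] - z[idx]) ** 2
    noise = float(np.std(f[:idx])) if idx > 1 else 0.0
    excluded = rise < snr_threshold * noise or c == 0.0
    if excluded:
        logger.warning("no detectable contact (rise %.3g vs noise %.3g); curve excluded", rise, noise)
    return ContactPointResult(
        offset=float(z[idx]), contact_index=idx, baseline=baseline, excluded=excluded, sse=sse
    )


# ---------------------------------------------------------------------------
# Magnetic twisting cytometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwistingRecord:
    """Synchronously sampled specific torque (Pa) and bead displacement (nm)."""

    times: np.ndarray              # seconds
    specific_torque: np.ndarray    # Pa
    bead_displacement: np.ndarray  # nm
    driving_frequency: float       # Hz

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        tq = np.asarray(self.specific_torque, dtype=float)
        d = np.asarray(self.bead_displacement, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "specific_torque", tq)
        object.__setattr__(self, "bead_displacement", d)
        if t.ndim != 1 or tq.shape != t.shape or d.shape != t.shape:
            raise DataError("torque and displacement must share the sampling grid")
        if self.driving_frequency <= 0:
            raise ConfigurationError("driving_frequency must be > 0")


def _sinusoid_amplitude(times: np.ndarray, signal: np.ndarray, freq: float) -> float:
    """Amplitude at ``freq`` from a least-squares fit of a·sin + b·cos + offset."""
    w = 2.0 * math.pi * freq
    design = np.column_stack([np.sin(w * times), np.cos(w * times), np.ones_like(times)])
    coef, *_ = np.linalg.lstsq(design, signal, rcond=None)
    return float(np.hypot(coef[0], coef[1]))


def mtc_stiffness(record: TwistingRecord, noise_floor: float = 0.0) -> float:
    """Cell stiffness (Pa/nm): torque amplitude over displacement amplitude.

    Both amplitudes are extracted at the driving frequency by linear
    least squares, which makes the ratio invariant to any phase lag of
    the viscoelastic response.  Requires ≥ 2 full periods of recording;
    a displacement amplitude at or below ``noise_floor`` (nm, the
    instrument's optical resolution) is unmeasurable.
    """
    duration = float(record.times[-1] - record.times[0])
    if duration < 2.0 / record.driving_frequency:
        raise InsufficientDataError(
            f"need ≥ 2 periods ({2.0 / record.driving_frequency:.3g} s); got {duration:.3g} s"
        )
    torque_amp = _sinusoid_amplitude(record.times, record.specific_torque, record.driving_frequency)
    disp_amp = _sinusoid_amplitude(record.times, record.bead_displacement, record.driving_frequency)
    if disp_amp <= noise_floor:
        raise UnmeasurableSignalError(
            f"displacement amplitude {disp_amp:.3g} nm at/below noise floor {noise_floor:.3g} nm"
        )
    return torque_amp / disp_amp
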