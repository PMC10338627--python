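"""Expression-side arithmetic: ΔΔCt, NanoString normalisation, fluorescence
summaries, positivity percentages, and viability/densitometry ratios.

These are the small, exactly-specified calculations that accompany the
imaging and mechanics assays: relative qPCR quantification against a
housekeeping gene, positive-control count normalisation with the
"reads < 40 are undetected" rule, per-cell integrated density and mean
fluorescent intensity, fraction of marker-positive cells, and simple
normalised ratios for western-blot densitometry and anoikis-resistance
viability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, InsufficientDataError

logger = logging.getLogger(__name__)

CT_COLUMNS = (
    "ct_target_treated",
    "ct_housekeeping_treated",
    "ct_target_control",
    "ct_housekeeping_control",
)

#: NanoString rule: raw transcript reads below this are undetected.
UNDETECTED_THRESHOLD = 40


# ---------------------------------------------------------------------------
# Delta-delta Ct
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DdctResult:
    """Per-replicate and summary relative expression.

    ``fold_change`` per replicate is 2^(−ΔΔCt).  The summary fold is
    computed from the mean ΔΔCt (i.e. the geometric mean of replicate
    folds), the natural scale for a log-linear quantity.
    """

    ddct: np.ndarray
    fold_change: np.ndarray
    mean_ddct: float
    fold_change_summary: float
    n_replicates: int
    n_excluded: int


def delta_delta_ct(table: pd.DataFrame) -> DdctResult:
    """Relative expression by the delta-delta Ct method.

    Per replicate: ΔCt = Ct_target − Ct_housekeeping within each
    condition; ΔΔCt = ΔCt_treated − ΔCt_control; fold = 2^(−ΔΔCt).
    Replicates with any missing Ct are excluded with a warning.
    """
    missing_cols = [c for c in CT_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ConfigurationError(f"Ct table missing columns: {missing_cols}")
    values = table.loc[:, list(CT_COLUMNS)].astype(float)
    complete = values.notna().all(axis=1)
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.warning("excluding %d replicate(s) with missing Ct values", n_excluded)
    values = values[complete]
    if values.empty:
        raise InsufficientDataError("no complete replicates in Ct table")
    if not (values > 0).all().all() or not np.isfinite(values.to_numpy()).all():
        raise DataError("Ct values must be finite and > 0")
    dct_treated = values["ct_target_treated"] - values["ct_housekeeping_treated"]
    dct_control = values["ct_target_control"] - values["ct_housekeeping_control"]
    ddct = (dct_treated - dct_control).to_numpy()
    fold = np.exp2(-ddct)
    mean_ddct = float(ddct.mean())
    return DdctResult(
        ddct=ddct,
        fold_change=fold,
        mean_ddct=mean_ddct,
        fold_change_summary=float(2.0 ** (-mean_ddct)),
        n_replicates=int(ddct.size),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# NanoString positive-control normalisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NanostringResult:
    normalized: pd.DataFrame
    undetected: pd.DataFrame      # boolean, aligned with `normalized`
    scale_factors: pd.Series
    excluded_samples: tuple


def nanostring_normalize(
    counts: pd.DataFrame, positive_controls: Sequence[str]
) -> NanostringResult:
    """Scale each sample by its positive-control total; flag low counts.

    ``counts`` is genes × samples with nonnegative integer raw counts and
    ``positive_controls`` names the spike-in control rows.  Raw counts
    below :data:`UNDETECTED_THRESHOLD` (40) are flagged undetected
    *before* scaling.  Each sample is multiplied by
    (mean positive-control total across samples) / (its own total), which
    preserves within-sample count ratios; a sample whose control total is
    zero is excluded and reported.
    """
    pc = [g for g in positive_controls if g in counts.index]
    if not pc:
        raise ConfigurationError("no positive-control genes found in count matrix")
    arr = counts.to_numpy()
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise DataError("raw counts must be nonnegative integers")
    totals = counts.loc[pc].sum(axis=0).astype(float)
    good = totals > 0
    excluded = tuple(totals.index[~good])
    if excluded:
        logger.error("samples with zero positive-control total excluded: %s", list(excluded))
    kept = counts.loc[:, good]
    undetected = kept < UNDETECTED_THRESHOLD
    factors = totals[good].mean() / totals[good]
    normalized = kept * factors
    return NanostringResult(
        normalized=normalized,
        undetected=undetected,
        scale_factors=factors,
        excluded_samples=excluded,
    )


# ---------------------------------------------------------------------------
# Per-cell fluorescence summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellIntensityProfile:
    """All pixel intensities of one segmented cell, plus exposure metadata.

    Exposure time (ms) is carried as metadata only; intensities acquired
    at different exposures are not rescaled against each other.
    """

    cell_id: str
    pixel_intensities: np.ndarray
    exposure_time_ms: float | None = None

    def __post_init__(self):
        px = np.asarray(self.pixel_intensities, dtype=float)
        object.__setattr__(self, "pixel_intensities", px)
        if px.ndim != 1 or px.size < 1:
            raise InsufficientDataError(f"cell {self.cell_id!r}: needs ≥ 1 pixel")
        if np.any(px < 0) or not np.all(np.isfinite(px)):
            raise DataError(f"cell {self.cell_id!r}: intensities must be finite and ≥ 0")


def integrated_density(profile: CellIntensityProfile) -> float:
    """IntDen: sum of fluorescence intensity over all pixels of the cell."""
    return float(profile.pixel_intensities.sum())


def mean_fluorescent_intensity(profile: CellIntensityProfile) -> float:
    """MFI: mean fluorescence per pixel; IntDen / pixel count identically."""
    return float(profile.pixel_intensities.mean())


# ---------------------------------------------------------------------------
# Ratios and percentages
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Positivity:
    percent: float        # exact value, 100·n_positive/n_total
    percent_rounded: int  # nearest integer percent, as reported in figures
    n_positive: int
    n_total: int


def positivity_fraction(n_positive: int, n_total: int) -> Positivity:
    """Percentage of marker-positive cells, exact and rounded."""
    if n_total <= 0:
        raise InsufficientDataError("n_total must be > 0")
    if not 0 <= n_positive <= n_total:
        raise DataError(f"need 0 ≤ n_positive ≤ n_total, got {n_positive}/{n_total}")
    exact = 100.0 * n_positive / n_total
    return Positivity(
        percent=exact,
        percent_rounded=int(round(exact)),
        n_positive=int(n_positive),
        n_total=int(n_total),
    )


def anoikis_resistance(
    challenged_signal: float, control_signal: float, background: float = 0.0
) -> float:
    """Viability of suspension-challenged cells relative to adherent controls.

    Optionally background-subtracted: (challenged − b) / (control − b).
    """
    num = challenged_signal - background
    den = control_signal - background
    if den <= 0:
        raise DataError("control signal must exceed background for a defined ratio")
    if num < 0:
        logger.warning("challenged signal below background; clamping ratio to 0")
        return 0.0
    return num / den


def densitometry_ratio(band_density: float, loading_control_density: float) -> float:
    """Band intensity normalised to its lane's loading control."""
    if loading_control_density <= 0:
        raise DataError("loading control density must be > 0")
    if band_density < 0:
        raise DataError("band density must be ≥ 0")
    return band_density / loading_control_density


def densitometry_batch(
    band_densities: Sequence[float],
    loading_control_densities: Sequence[float],
    reference_lane: int = 0,
) -> np.ndarray:
    """Per-lane loading-normalised ratios re-expressed relative to one lane.

    The reference lane maps to exactly 1.0 by construction.
    """
    bands = np.asarray(band_densities, dtype=float)
    loads = np.asarray(loading_control_densities, dtype=float)
    if bands.shape != loads.shape or bands.ndim != 1 or bands.size == 0:
        raise DataError("band and loading-control vectors must be equal-length and nonempty")
    ratios = np.array([densitometry_ratio(b, l) for b, l in zip(bands, loads)])
    if not 0 <= reference_lane < ratios.size:
        raise ConfigurationError(f"reference_lane {reference_lane} out of range")
    ref = ratios[reference_lane]
    if ref == 0:
        raise DataError("reference lane has zero normalised density")
    return ratios / ref
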