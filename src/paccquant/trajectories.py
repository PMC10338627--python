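"""Single-cell migration trajectories and per-cell motility metrics.

A :class:`Trajectory` is one cell's time-ordered 2D track (minutes, µm)
from time-lapse imaging, optionally annotated with the cell's 2D surface
area and exclusion flags (division, apoptosis, left the field of view).
The metrics below are the standard per-cell motility readouts:

* accumulated distance — total path length (µm),
* Euclidean distance  — net start-to-end displacement (µm),
* directness          — Euclidean / accumulated, 1 for a straight path.

Cohort operations translate tracks to the origin for spider plots, drop
flagged cells, and regress any metric against cell area.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError, InsufficientDataError

logger = logging.getLogger(__name__)

#: Exclusion flags recognised on a trajectory.
VALID_FLAGS = frozenset({"divided", "apoptosed", "left_frame"})

MetricName = Literal["accumulated", "euclidean", "directness"]


@dataclass(frozen=True)
class Trajectory:
    """One cell's track: strictly increasing times (min) and x/y positions (µm).

    Parameters
    ----------
    cell_id:
        Unique identifier within a :class:`TrajectorySet`.
    times:
        Sample times in minutes, strictly increasing.
    xy:
        ``(n, 2)`` array of positions in µm, Cartesian convention (+y up).
    area:
        Optional 2D surface area of the cell in µm².
    flags:
        Subset of :data:`VALID_FLAGS`; any flag excludes the cell from
        cohort analysis.
    """

    cell_id: str
    times: np.ndarray
    xy: np.ndarray
    area: float | None = None
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        xy = np.asarray(self.xy, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "xy", xy)
        object.__setattr__(self, "flags", frozenset(self.flags))
        if times.ndim != 1 or xy.ndim != 2 or xy.shape != (times.size, 2):
            raise DataError(
                f"trajectory {self.cell_id!r}: times {times.shape} and xy {xy.shape} "
                "must be (n,) and (n, 2)"
            )
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise DataError(f"trajectory {self.cell_id!r}: times must be strictly increasing")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(xy)):
            raise DataError(f"trajectory {self.cell_id!r}: non-finite coordinates")
        if self.area is not None and not self.area > 0:
            raise DataError(f"trajectory {self.cell_id!r}: area must be > 0, got {self.area}")
        bad = self.flags - VALID_FLAGS
        if bad:
            raise DataError(f"trajectory {self.cell_id!r}: unknown flags {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class TrajectorySet:
    """A cohort of trajectories acquired under one condition.

    ``condition_label`` follows the serum-condition shorthand used for
    chemotaxis chambers: ``"+/+"`` (uniform serum), ``"-/-"`` (uniform
    serum-free), ``"-/+"`` (serum gradient).  ``gradient_axis`` is the unit
    vector pointing up the chemoattractant gradient, required for any
    directional statistic.
    """

    trajectories: tuple
    condition_label: str = "-/+"
    gradient_axis: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "trajectories", tuple(self.trajectories))
        ids = [t.cell_id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate cell ids in set: {dupes}")
        if self.gradient_axis is not None:
            g = np.asarray(self.gradient_axis, dtype=float)
            norm = float(np.hypot(*g))
            if g.shape != (2,) or norm == 0 or not np.isfinite(norm):
                raise ConfigurationError("gradient_axis must be a finite nonzero 2-vector")
            object.__setattr__(self, "gradient_axis", g / norm)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)


def _require_samples(traj: Trajectory, n: int, what: str) -> None:
    if traj.n_samples < n:
        raise InsufficientDataError(
            f"{what} requires ≥ {n} samples; trajectory {traj.cell_id!r} has {traj.n_samples}"
        )


def accumulated_distance(traj: Trajectory) -> float:
    """Total path length in µm: the sum of consecutive segment lengths."""
    _require_samples(traj, 2, "accumulated distance")
    steps = np.diff(traj.xy, axis=0)
    return float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))


def euclidean_distance(traj: Trajectory) -> float:
    """Net start-to-end displacement in µm."""
    _require_samples(traj, 2, "Euclidean distance")
    d = traj.xy[-1] - traj.xy[0]
    return float(np.hypot(d[0], d[1]))


def directness(traj: Trajectory) -> float:
    """Euclidean / accumulated distance, in [0, 1].

    Returns NaN for a cell that never moved (0/0 is undefined); such cells
    are reported as missing, never as 0 or 1.
    """
    acc = accumulated_distance(traj)
    if acc == 0.0:
        return math.nan
    return euclidean_distance(traj) / acc


def endpoint_displacement(traj: Trajectory) -> np.ndarray:
    """Final-minus-first position vector (µm) — the spider-plot endpoint."""
    _require_samples(traj, 2, "endpoint displacement")
    return traj.xy[-1] - traj.xy[0]


def translate_to_origin(tset: TrajectorySet) -> TrajectorySet:
    """Translate every trajectory so its first sample sits at (0, 0).

    This is the spider-plot construction; inter-sample displacements, and
    hence all distance metrics, are unchanged.
    """
    moved = tuple(replace(t, xy=t.xy - t.xy[0]) for t in tset.trajectories)
    return replace(tset, trajectories=moved)


def spider_table(tset: TrajectorySet) -> pd.DataFrame:
    """Tidy per-sample table of origin-translated coordinates for plotting."""
    shifted = translate_to_origin(tset)
    frames = [
        pd.DataFrame(
            {
                "cell_id": t.cell_id,
                "time_min": t.times,
                "x_um": t.xy[:, 0],
                "y_um": t.xy[:, 1],
            }
        )
        for t in shifted
    ]
    if not frames:
        return pd.DataFrame(columns=["cell_id", "time_min", "x_um", "y_um"])
    return pd.concat(frames, ignore_index=True)


def apply_exclusions(tset: TrajectorySet) -> TrajectorySet:
    """Drop cells that divided, apoptosed, or left the frame.

    Idempotent; the number of removals is logged so cohort n stays auditable.
    """
    kept = tuple(t for t in tset.trajectories if not t.flags)
    removed = len(tset.trajectories) - len(kept)
    if removed:
        logger.info(
            "condition %s: excluded %d of %d cells (division/apoptosis/out-of-frame)",
            tset.condition_label, removed, len(tset.trajectories),
        )
    if kept == tset.trajectories:
        return tset
    if not kept:
        logger.warning("condition %s: all %d cells excluded", tset.condition_label, removed)
    return replace(tset, trajectories=kept)


def metrics_table(tset: TrajectorySet) -> pd.DataFrame:
    """Per-cell motility metrics as a tidy table (one row per cell).

    Columns: cell_id, n_samples, accumulated_um, euclidean_um, directness,
    area_um2.  Directness is NaN for stationary cells.
    """
    rows = []
    for t in tset:
        rows.append(
            {
                "cell_id": t.cell_id,
                "n_samples": t.n_samples,
                "accumulated_um": accumulated_distance(t),
                "euclidean_um": euclidean_distance(t),
                "directness": directness(t),
                "area_um2": math.nan if t.area is None else t.area,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cell_id", "n_samples", "accumulated_um", "euclidean_um",
                 "directness", "area_um2"],
    )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


_METRIC_FUNCS = {
    "accumulated": accumulated_distance,
    "euclidean": euclidean_distance,
    "directness": directness,
}


def regress_metric_vs_area(tset: TrajectorySet, metric: MetricName) -> RegressionResult:
    """OLS fit of a per-cell motility metric against 2D cell surface area.

    Cells without an area annotation, or with an undefined metric value,
    are omitted.  Requires ≥ 3 usable cells and non-constant areas.
    """
    if metric not in _METRIC_FUNCS:
        raise ConfigurationError(f"unknown metric {metric!r}; choose from {sorted(_METRIC_FUNCS)}")
    func = _METRIC_FUNCS[metric]
    areas, values = [], []
    for t in tset:
        if t.area is None:
            continue
        v = func(t)
        if math.isnan(v):
            continue
        areas.append(t.area)
        values.append(v)
    if len(areas) < 3:
        raise InsufficientDataError(
            f"metric-vs-area regression needs ≥ 3 cells with area; got {len(areas)}"
        )
    areas_arr = np.asarray(areas)
    if np.ptp(areas_arr) == 0:
        raise DataError("all cell areas identical: regressor is degenerate")
    fit = stats.linregress(areas_arr, np.asarray(values))
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(areas),
    )
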