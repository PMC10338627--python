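"""Readers and writers for trajectory tables, plus configuration loading.

Tracking tools export flat text tables (track id, frame, x, y) whose
column names, pixel calibration, and y-axis convention vary by tool and
version, so the layout is configuration — a :class:`TrajectoryTableDialect`
— not hard-coded.  Imported coordinates are converted to µm/minutes and
flipped to Cartesian (+y up) when the source uses the image convention
(+y down), so "up the gradient" means the same thing everywhere.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError, SchemaError
from .trajectories import Trajectory, TrajectorySet, VALID_FLAGS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrajectoryTableDialect:
    """How to interpret one tracking export.

    ``frame_or_time`` is a frame index by default; with
    ``time_is_frames=False`` it is read directly as minutes.  ``flags``
    optionally names a column holding comma-separated exclusion flags;
    ``area`` a per-row cell-area column (µm², constant within a track).
    """

    track_id: str = "track_id"
    frame_or_time: str = "frame"
    x: str = "x"
    y: str = "y"
    pixel_size: float = 1.0            # µm per pixel
    frame_interval: float = 30.0       # minutes per frame
    time_is_frames: bool = True
    y_axis_direction: str = "cartesian_up"   # or "image_down"
    gradient_axis: tuple | None = None
    flags: str | None = None
    area: str | None = None

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size: must be > 0")
        if self.frame_interval <= 0:
            raise ConfigurationError("frame_interval: must be > 0")
        if self.y_axis_direction not in ("cartesian_up", "image_down"):
            raise ConfigurationError(
                "y_axis_direction: must be 'cartesian_up' or 'image_down'"
            )


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_trajectories(
    path: str | Path,
    dialect: TrajectoryTableDialect = TrajectoryTableDialect(),
    condition_label: str = "-/+",
) -> TrajectorySet:
    """Load a tracking export into a :class:`TrajectorySet` (µm, minutes).

    Malformed rows (non-numeric coordinates) are dropped with a logged
    line number; a missing mapped column is a schema error; non-monotone
    frames within a track are a data error.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    df = _read_table(path)
    needed = [dialect.track_id, dialect.frame_or_time, dialect.x, dialect.y]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")

    numeric_cols = [dialect.frame_or_time, dialect.x, dialect.y]
    coerced = df[numeric_cols].apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1)
    if bad.any():
        for idx in df.index[bad]:
            # +2: header line plus 1-based numbering
            logger.warning("%s: dropping malformed row at line %d", path, idx + 2)
    df = df.loc[~bad].copy()
    df[numeric_cols] = coerced.loc[~bad]

    trajectories = []
    for track_id, group in df.groupby(dialect.track_id, sort=True):
        group = group.sort_index()  # file order within a track
        frames = group[dialect.frame_or_time].to_numpy(dtype=float)
        if np.any(np.diff(frames) <= 0):
            raise DataError(f"{path}: non-monotone frames within track {track_id!r}")
        times = frames * dialect.frame_interval if dialect.time_is_frames else frames
        x = group[dialect.x].to_numpy(dtype=float) * dialect.pixel_size
        y = group[dialect.y].to_numpy(dtype=float) * dialect.pixel_size
        if dialect.y_axis_direction == "image_down":
            y = -y
        flags: frozenset = frozenset()
        if dialect.flags and dialect.flags in group.columns:
            raw = ",".join(str(v) for v in group[dialect.flags].dropna().unique())
            flags = frozenset(f for f in (s.strip() for s in raw.split(",")) if f in VALID_FLAGS)
        area = None
        if dialect.area and dialect.area in group.columns:
            vals = pd.to_numeric(group[dialect.area], errors="coerce").dropna()
            if not vals.empty:
                area = float(vals.iloc[0])
        trajectories.append(
            Trajectory(cell_id=str(track_id), times=times, xy=np.column_stack([x, y]),
                       area=area, flags=flags)
        )
    return TrajectorySet(
        trajectories=tuple(trajectories),
        condition_label=condition_label,
        gradient_axis=dialect.gradient_axis,
    )


def write_trajectories(tset: TrajectorySet, path: str | Path) -> None:
    """Write a set as CSV in the package's canonical dialect.

    Columns: track_id, frame, x, y (µm, Cartesian +y up, one frame per
    sample index), plus flags/area when present.  Reading the file back
    with the matching dialect (pixel_size=1, frame_interval equal to the
    set's sampling interval) round-trips exactly.
    """
    rows = []
    for t in tset:
        interval = float(t.times[1] - t.times[0]) if t.n_samples > 1 else 1.0
        for j in range(t.n_samples):
            rows.append(
                {
                    "track_id": t.cell_id,
                    "frame": t.times[j] / interval,
                    "x": t.xy[j, 0],
                    "y": t.xy[j, 1],
                    "flags": ",".join(sorted(t.flags)),
                    "area": "" if t.area is None else t.area,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def canonical_dialect(frame_interval: float = 30.0,
                      gradient_axis: tuple | None = None) -> TrajectoryTableDialect:
    """Dialect matching :func:`write_trajectories` output (µm, Cartesian)."""
    return TrajectoryTableDialect(
        pixel_size=1.0,
        frame_interval=frame_interval,
        y_axis_direction="cartesian_up",
        gradient_axis=gradient_axis,
        flags="flags",
        area="area",
    )


def load_config(path: str | Path) -> dict:
    """Load a flat YAML/JSON configuration file into a dict."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return data
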