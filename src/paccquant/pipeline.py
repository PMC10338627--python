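"""End-to-end analysis pipeline: exclusions → metrics → chemotaxis,
with optional biomechanics and expression stages, driven by one config.

A run is a pure function of (inputs, config): every random stage draws
from a seed recorded in the run log, and rerunning with the same config
produces byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .biomechanics import compute_msd, fit_diffusion_coefficient, fit_hertz
from .chemotaxis import build_report, classify_chemotaxis
from .errors import ConfigurationError
from .expression import delta_delta_ct
from .io import canonical_dialect, read_trajectories, TrajectoryTableDialect
from .synthetic import (
    BeadSimConfig,
    HertzSimConfig,
    MigrationSimConfig,
    simulate_bead_tracks,
    simulate_ct_table,
    simulate_force_curve,
    simulate_trajectories,
)
from .trajectories import apply_exclusions, metrics_table, spider_table

logger = logging.getLogger(__name__)

CONDITION_LABELS = ("+/+", "-/-", "-/+")


def _load_condition(label: str, spec: dict, seed: int, gradient_axis):
    if "input" in spec:
        dialect_kwargs = dict(spec.get("dialect", {}))
        if gradient_axis is not None:
            dialect_kwargs.setdefault("gradient_axis", tuple(gradient_axis))
        dialect = (
            TrajectoryTableDialect(**dialect_kwargs)
            if dialect_kwargs
            else canonical_dialect(gradient_axis=tuple(gradient_axis) if gradient_axis else None)
        )
        return read_trajectories(spec["input"], dialect, condition_label=label)
    if "simulate" in spec:
        params = dict(spec["simulate"])
        params.setdefault("seed", seed)
        if gradient_axis is not None:
            params.setdefault("gradient_axis", tuple(gradient_axis))
        return simulate_trajectories(MigrationSimConfig(**params), condition_label=label)
    raise ConfigurationError(f"condition {label!r}: needs an 'input' path or a 'simulate' block")


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the configured stages and write the report bundle.

    Config keys: ``seed`` (int), ``gradient_axis`` ([gx, gy]),
    ``conditions`` (mapping of condition label → {input|simulate, ...}),
    optional ``chemotaxis`` ({alpha, near_zero_epsilon, n_reps}),
    ``beads``/``afm``/``expression`` blocks for the optional stages.

    Writes per-condition metric and spider CSVs, a chemotaxis report
    JSON (when all three conditions are present), optional stage outputs,
    and ``run_log.json``; returns a dict of output paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    gradient_axis = config.get("gradient_axis")
    conditions_cfg = config.get("conditions", {})
    if not conditions_cfg:
        raise ConfigurationError("config must define at least one condition")

    outputs: dict = {}
    excluded_counts: dict = {}
    sets = {}
    for offset, (label, spec) in enumerate(sorted(conditions_cfg.items())):
        tset = _load_condition(label, spec, seed + offset, gradient_axis)
        n_before = len(tset)
        tset = apply_exclusions(tset)
        excluded_counts[label] = n_before - len(tset)
        sets[label] = tset
        slug = label.replace("/", "").replace("+", "p").replace("-", "m")
        metrics_path = outdir / f"metrics_{slug}.csv"
        metrics_table(tset).to_csv(metrics_path, index=False)
        spider_path = outdir / f"spider_{slug}.csv"
        spider_table(tset).to_csv(spider_path, index=False)
        outputs[f"metrics_{label}"] = str(metrics_path)
        outputs[f"spider_{label}"] = str(spider_path)

    chemo_cfg = dict(config.get("chemotaxis", {}))
    want_chemotaxis = chemo_cfg.pop("enabled", True) and set(CONDITION_LABELS) <= set(sets)
    if want_chemotaxis:
        if gradient_axis is None:
            raise ConfigurationError("chemotaxis stage requires a gradient_axis in the config")
        n_reps = int(chemo_cfg.pop("n_reps", 10_000))
        reports = {
            label: build_report(sets[label], n_reps=n_reps, seed=seed + 100 + i)
            for i, label in enumerate(CONDITION_LABELS)
        }
        verdict = classify_chemotaxis(reports, **chemo_cfg)
        payload = {
            "reports": {label: r.to_dict() for label, r in reports.items()},
            "classification": verdict.to_dict(),
        }
        chemo_path = outdir / "chemotaxis_report.json"
        chemo_path.write_text(json.dumps(payload, indent=2))
        outputs["chemotaxis_report"] = str(chemo_path)

    if "beads" in config:
        bead_cfg = dict(config["beads"])
        max_lag = float(bead_cfg.pop("max_lag", 5.0))
        bead_cfg.setdefault("seed", seed + 1000)
        tracks = simulate_bead_tracks(BeadSimConfig(**bead_cfg))
        curve = compute_msd(tracks, max_lag=max_lag)
        d_hat, r2 = fit_diffusion_coefficient(curve)
        msd_path = outdir / "msd.csv"
        np.savetxt(
            msd_path,
            np.column_stack([curve.lags, curve.msd, curve.n_pairs_per_lag]),
            delimiter=",",
            header="lag_s,msd_nm2,n_pairs",
            comments="",
        )
        (outdir / "msd_fit.json").write_text(
            json.dumps({"diffusion_nm2_per_s": d_hat, "r_squared": r2}, indent=2)
        )
        outputs["msd"] = str(msd_path)
        outputs["msd_fit"] = str(outdir / "msd_fit.json")

    if "afm" in config:
        afm_cfg = dict(config["afm"])
        afm_cfg.setdefault("seed", seed + 2000)
        fit = fit_hertz(simulate_force_curve(HertzSimConfig(**afm_cfg)))
        hertz_path = outdir / "hertz_fit.json"
        hertz_path.write_text(json.dumps(dataclasses.asdict(fit), indent=2))
        outputs["hertz_fit"] = str(hertz_path)

    if "expression" in config:
        expr_cfg = dict(config["expression"])
        expr_cfg.setdefault("seed", seed + 3000)
        result = delta_delta_ct(simulate_ct_table(**expr_cfg))
        expr_path = outdir / "ddct.json"
        expr_path.write_text(
            json.dumps(
                {
                    "fold_change_per_replicate": result.fold_change.tolist(),
                    "fold_change_summary": result.fold_change_summary,
                    "mean_ddct": result.mean_ddct,
                    "n_excluded": result.n_excluded,
                },
                indent=2,
            )
        )
        outputs["ddct"] = str(expr_path)

    log_path = outdir / "run_log.json"
    log_path.write_text(
        json.dumps(
            {
                "package_version": __version__,
                "seed": seed,
                "excluded_cells": excluded_counts,
                "conditions": {label: len(sets[label]) for label in sets},
                "outputs": outputs,
            },
            indent=2,
        )
    )
    outputs["run_log"] = str(log_path)
    return outputs
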