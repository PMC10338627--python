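"""Circular statistics and the chemotaxis decision procedure.

Directional response of a cell cohort to a chemoattractant gradient is
quantified from the origin-translated endpoint of each cell's trajectory:

* **Rayleigh test** — uniformity of endpoint *angles*; the null is
  circular uniformity (no preferred direction).
* **Rayleigh test for vector data** — Moore's rank-based modification,
  which additionally weights each endpoint by its distance from the
  origin (magnitudes are replaced by ranks; the resultant of rank-weighted
  unit vectors is normalised by n^{3/2}).  Its p-value is obtained by
  seeded Monte-Carlo simulation of the null.
* **Forward migration indices** — per cell, the endpoint displacement
  component parallel (∥) or perpendicular (⊥) to the gradient divided by
  that cell's accumulated path length; the cohort FMI is the mean over
  cells.  Positive ∥FMI is net movement up the gradient.

A cohort is called *chemotactic* only when the gradient condition is
directional while both uniform-media controls are not, and the FMI
pattern matches: gradient ∥FMI significantly above both control ∥FMIs and
above its own ⊥FMI, with the ⊥FMI and all control FMIs close to zero.

Group comparisons follow the nonparametric conventions of the field:
two-sided Mann–Whitney U for two groups, Kruskal–Wallis for several,
with α = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError
from .trajectories import TrajectorySet, accumulated_distance, endpoint_displacement

__all__ = [
    "EndpointVector",
    "endpoint_vectors",
    "FmiResult",
    "forward_migration_indices",
    "RayleighResult",
    "rayleigh_test",
    "MooreResult",
    "moore_statistic",
    "moore_null_statistics",
    "rayleigh_test_vector",
    "ChemotaxisReport",
    "build_report",
    "ChemotaxisVerdict",
    "classify_chemotaxis",
    "compare_groups",
    "compare_many",
]

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class EndpointVector:
    """Origin-translated final displacement of one trajectory (µm)."""

    dx: float
    dy: float

    @property
    def angle(self) -> float:
        """Direction in radians, in (−π, π]."""
        return math.atan2(self.dy, self.dx)

    @property
    def magnitude(self) -> float:
        return math.hypot(self.dx, self.dy)


def endpoint_vectors(tset: TrajectorySet) -> list[EndpointVector]:
    """Spider-plot endpoints of every trajectory in the set."""
    out = []
    for t in tset:
        d = endpoint_displacement(t)
        out.append(EndpointVector(float(d[0]), float(d[1])))
    return out


# ---------------------------------------------------------------------------
# Forward migration indices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FmiResult:
    """Cohort forward migration indices with the per-cell components.

    ``parallel_values[i]`` and ``perpendicular_values[i]`` are the i-th
    usable cell's endpoint displacement components along/across the
    gradient divided by its accumulated distance; they satisfy
    ∥² + ⊥² = directness² cell by cell.
    """

    fmi_parallel: float
    fmi_perpendicular: float
    parallel_values: np.ndarray
    perpendicular_values: np.ndarray
    cell_ids: tuple
    n_missing: int = 0


def forward_migration_indices(tset: TrajectorySet) -> FmiResult:
    """Per-cell and cohort FMIs along the declared gradient axis.

    Cells with zero accumulated distance have an undefined FMI and are
    reported missing (counted in ``n_missing``), mirroring the directness
    convention.
    """
    if tset.gradient_axis is None:
        raise ConfigurationError(
            f"condition {tset.condition_label!r}: gradient_axis required for FMI"
        )
    g = tset.gradient_axis
    perp = np.array([-g[1], g[0]])  # +90° rotation
    par_vals, perp_vals, ids = [], [], []
    missing = 0
    for t in tset:
        acc = accumulated_distance(t)
        if acc == 0.0:
            missing += 1
            continue
        d = endpoint_displacement(t)
        par_vals.append(float(d @ g) / acc)
        perp_vals.append(float(d @ perp) / acc)
        ids.append(t.cell_id)
    if not par_vals:
        raise InsufficientDataError(
            f"condition {tset.condition_label!r}: no cells with nonzero path length"
        )
    par = np.asarray(par_vals)
    per = np.asarray(perp_vals)
    return FmiResult(
        fmi_parallel=float(par.mean()),
        fmi_perpendicular=float(per.mean()),
        parallel_values=par,
        perpendicular_values=per,
        cell_ids=tuple(ids),
        n_missing=missing,
    )


# ---------------------------------------------------------------------------
# Rayleigh test (angles only)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RayleighResult:
    mean_resultant_length: float
    z: float
    p: float
    n: int


def rayleigh_test(angles: Sequence[float]) -> RayleighResult:
    """Rayleigh test of circular uniformity on a sample of angles (radians).

    The statistic is Z = n·R̄² with R̄ the mean resultant length.  The
    p-value uses the small-sample-corrected exponential approximation

        p ≈ exp(−Z)·[1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)]

    clamped to [0, 1].
    """
    a = np.asarray(angles, dtype=float)
    if a.ndim != 1 or a.size < 3 or not np.all(np.isfinite(a)):
        raise InsufficientDataError("Rayleigh test needs ≥ 3 finite angles")
    n = a.size
    c = np.cos(a).sum()
    s = np.sin(a).sum()
    rbar = float(np.hypot(c, s)) / n
    z = n * rbar**2
    p = math.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    return RayleighResult(rbar, z, min(1.0, max(0.0, p)), n)


# ---------------------------------------------------------------------------
# Rayleigh test for vector data (Moore's rank-based modification)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MooreResult:
    statistic: float
    p: float
    n: int
    n_reps: int
    ties_in_magnitude: bool


def moore_statistic(angles: np.ndarray, magnitudes: np.ndarray) -> tuple[float, bool]:
    """Moore's R*: rank-weighted resultant length, normalised by n^{3/2}.

    Magnitudes are replaced by mid-ranks (ties noted); the statistic is
    |Σ rᵢ·(cosθᵢ, sinθᵢ)| / n^{3/2}.
    """
    ranks = stats.rankdata(magnitudes)  # mid-ranks on ties
    ties = np.unique(magnitudes).size < magnitudes.size
    n = angles.size
    x = float(np.sum(ranks * np.cos(angles)))
    y = float(np.sum(ranks * np.sin(angles)))
    return math.hypot(x, y) / n**1.5, ties


def moore_null_statistics(
    n: int, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo sample of Moore's R* under the null of uniform directions.

    Under the null the angles are uniform and independent of the
    magnitude ranks, so the rank vector can be held at (1, …, n) while the
    angles are redrawn; this is equivalent to permuting ranks against
    angles with uniform angles.  The null law depends only on n.
    """
    ranks = np.arange(1, n + 1, dtype=float)
    theta = rng.uniform(-math.pi, math.pi, size=(n_reps, n))
    x = np.cos(theta) @ ranks
    y = np.sin(theta) @ ranks
    return np.hypot(x, y) / n**1.5


def rayleigh_test_vector(
    endpoints: Sequence[EndpointVector],
    n_reps: int = 10_000,
    seed: int | np.random.Generator | None = 0,
    null_stats: np.ndarray | None = None,
) -> MooreResult:
    """Rayleigh test for vector data: directionality weighted by distance.

    Moore's modification replaces endpoint magnitudes by their ranks and
    tests the rank-weighted resultant against a seeded Monte-Carlo null
    (``n_reps`` draws; default 10 000).  A precomputed ``null_stats``
    sample (from :func:`moore_null_statistics`) may be supplied to share
    the null table across many tests of the same size.
    """
    if len(endpoints) < 3:
        raise InsufficientDataError("vector Rayleigh test needs ≥ 3 endpoints")
    angles = np.array([e.angle for e in endpoints])
    mags = np.array([e.magnitude for e in endpoints])
    observed, ties = moore_statistic(angles, mags)
    if null_stats is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        null_stats = moore_null_statistics(len(endpoints), n_reps, rng)
    n_reps = int(null_stats.size)
    # add-one rule keeps p > 0 and valid under Monte-Carlo
    p = (1.0 + float(np.count_nonzero(null_stats >= observed))) / (n_reps + 1.0)
    return MooreResult(observed, min(1.0, p), len(endpoints), n_reps, ties)


# ---------------------------------------------------------------------------
# Per-condition report and the chemotaxis verdict
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChemotaxisReport:
    """All directional statistics for one condition."""

    condition_label: str
    rayleigh_p: float
    rayleigh_vector_p: float
    fmi_parallel: float
    fmi_perpendicular: float
    fmi_parallel_values: np.ndarray
    fmi_perpendicular_values: np.ndarray
    n_cells: int
    ties_in_magnitude: bool = False

    def to_dict(self) -> dict:
        return {
            "condition_label": self.condition_label,
            "rayleigh_p": self.rayleigh_p,
            "rayleigh_vector_p": self.rayleigh_vector_p,
            "fmi_parallel": self.fmi_parallel,
            "fmi_perpendicular": self.fmi_perpendicular,
            "fmi_parallel_values": [float(v) for v in self.fmi_parallel_values],
            "fmi_perpendicular_values": [float(v) for v in self.fmi_perpendicular_values],
            "n_cells": self.n_cells,
            "ties_in_magnitude": self.ties_in_magnitude,
        }


def build_report(
    tset: TrajectorySet,
    n_reps: int = 10_000,
    seed: int | np.random.Generator | None = 0,
) -> ChemotaxisReport:
    """Compute both Rayleigh tests and the FMIs for one condition."""
    eps = endpoint_vectors(tset)
    angles = [e.angle for e in eps]
    ray = rayleigh_test(angles)
    moore = rayleigh_test_vector(eps, n_reps=n_reps, seed=seed)
    fmi = forward_migration_indices(tset)
    return ChemotaxisReport(
        condition_label=tset.condition_label,
        rayleigh_p=ray.p,
        rayleigh_vector_p=moore.p,
        fmi_parallel=fmi.fmi_parallel,
        fmi_perpendicular=fmi.fmi_perpendicular,
        fmi_parallel_values=fmi.parallel_values,
        fmi_perpendicular_values=fmi.perpendicular_values,
        n_cells=len(fmi.parallel_values),
        ties_in_magnitude=moore.ties_in_magnitude,
    )


@dataclass(frozen=True)
class ChemotaxisVerdict:
    verdict: bool
    criteria: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"verdict": self.verdict, "criteria": dict(self.criteria)}


def _one_sided_greater(a: np.ndarray, b: np.ndarray) -> float:
    """One-sided Mann–Whitney p for the alternative median(a) > median(b)."""
    return float(stats.mannwhitneyu(a, b, alternative="greater").pvalue)


def classify_chemotaxis(
    reports: Mapping[str, ChemotaxisReport],
    gradient_label: str = "-/+",
    control_labels: Sequence[str] = ("+/+", "-/-"),
    alpha: float = ALPHA_DEFAULT,
    near_zero_epsilon: float = 0.1,
    control_adjust: str = "bonferroni",
) -> ChemotaxisVerdict:
    """Apply the full chemotaxis decision rule across the three conditions.

    The cohort is chemotactic iff

    * **Rayleigh rule** — both Rayleigh variants are significant for the
      gradient condition at ``alpha`` and no control condition is
      significant.  Control significance is judged family-wise: with
      ``control_adjust="bonferroni"`` (default) a control test counts as
      significant only below ``alpha / m`` where m is the number of
      control p-values, so the chance of a spurious control rejection
      derailing the verdict stays at ``alpha``; ``"none"`` applies
      ``alpha`` per test.
    * **FMI criterion i** — gradient ∥FMI significantly higher than both
      control ∥FMIs (one-sided Mann–Whitney on per-cell components).
    * **FMI criterion ii** — gradient ∥FMI significantly higher than the
      gradient ⊥FMI, and |gradient ⊥FMI| ≤ ``near_zero_epsilon``.
    * **FMI criterion iii** — |∥FMI| and |⊥FMI| of both controls ≤
      ``near_zero_epsilon``.

    Returns the boolean verdict plus a per-criterion pass/fail trace.
    """
    missing = [lab for lab in (gradient_label, *control_labels) if lab not in reports]
    if missing:
        raise ConfigurationError(f"missing condition report(s): {missing}")
    if control_adjust not in ("bonferroni", "none"):
        raise ConfigurationError(f"control_adjust must be 'bonferroni' or 'none', got {control_adjust!r}")

    grad = reports[gradient_label]
    controls = [reports[lab] for lab in control_labels]

    # Rayleigh rule
    gradient_significant = grad.rayleigh_p < alpha and grad.rayleigh_vector_p < alpha
    control_ps = [p for r in controls for p in (r.rayleigh_p, r.rayleigh_vector_p)]
    thresh = alpha / len(control_ps) if control_adjust == "bonferroni" else alpha
    controls_nonsignificant = all(p >= thresh for p in control_ps)

    # FMI criteria
    crit_i = all(
        _one_sided_greater(grad.fmi_parallel_values, c.fmi_parallel_values) < alpha
        for c in controls
    )
    crit_ii = (
        _one_sided_greater(grad.fmi_parallel_values, grad.fmi_perpendicular_values) < alpha
        and abs(grad.fmi_perpendicular) <= near_zero_epsilon
    )
    crit_iii = all(
        abs(c.fmi_parallel) <= near_zero_epsilon
        and abs(c.fmi_perpendicular) <= near_zero_epsilon
        for c in controls
    )

    criteria = {
        "rayleigh_gradient_significant": gradient_significant,
        "rayleigh_controls_nonsignificant": controls_nonsignificant,
        "fmi_gradient_above_controls": crit_i,
        "fmi_parallel_above_perpendicular": crit_ii,
        "fmi_controls_near_zero": crit_iii,
    }
    verdict = all(criteria.values())
    return ChemotaxisVerdict(verdict=verdict, criteria=criteria)


# ---------------------------------------------------------------------------
# Nonparametric group comparisons
# ---------------------------------------------------------------------------

def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U comparison of two per-cell metric samples.

    Returns (U, p); exact p for small samples without ties, normal
    approximation otherwise (scipy's default policy).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("Mann–Whitney needs ≥ 2 values per group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def compare_many(groups: Iterable[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H test across several per-cell metric samples."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise InsufficientDataError("Kruskal–Wallis needs ≥ 2 groups with ≥ 2 values each")
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)
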