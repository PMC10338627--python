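"""Simulate a small cohort of migrating cells and compute per-cell
motility metrics: accumulated distance, Euclidean distance, directness.

Persistent walkers travel similar total path lengths but straighter
routes, so their directness (Euclidean/accumulated) is higher.
"""

from paccquant import MigrationSimConfig, metrics_table, simulate_trajectories

for label, persistence in [("meandering", 0.0), ("persistent", 0.8)]:
    cfg = MigrationSimConfig(n_cells=30, persistence=persistence, seed=1)
    df = metrics_table(simulate_trajectories(cfg))
    print(
        f"{label:11s} (persistence={persistence}): "
        f"accumulated {df.accumulated_um.mean():6.1f} um, "
        f"euclidean {df.euclidean_um.mean():6.1f} um, "
        f"directness {df.directness.mean():.3f}"
    )

print(
    "\nBoth cohorts walk comparable total distances (same speed model); the\n"
    "persistent cohort ends far further from its origin, hence higher directness."
)
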