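"""Spontaneous motion of cytoskeleton-anchored beads: compute the mean
squared displacement over lag time and recover the diffusion coefficient
from the linear fit MSD = 4*D*lag.

Faster bead diffusion reports a more dynamic (more actively remodelling)
cytoskeleton.
"""

from paccquant import BeadSimConfig, compute_msd, fit_diffusion_coefficient, simulate_bead_tracks

for label, d_true in [("quiescent cytoskeleton", 500.0), ("dynamic cytoskeleton", 2500.0)]:
    cfg = BeadSimConfig(n_beads=100, duration=60.0, diffusion_coefficient=d_true, seed=3)
    curve = compute_msd(simulate_bead_tracks(cfg), max_lag=3.0)
    d_hat, r2 = fit_diffusion_coefficient(curve)
    print(
        f"{label:23s}: true D = {d_true:6.0f} nm^2/s, "
        f"recovered D = {d_hat:7.1f} nm^2/s (R^2 = {r2:.4f})"
    )

print(
    "\nMSD grows linearly in lag (R^2 ~ 1), as expected for Brownian bead\n"
    "motion; slope/4 recovers the diffusion coefficient within a few percent."
)
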