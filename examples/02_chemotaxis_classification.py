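"""Three-condition chemotaxis experiment: uniform-serum control (+/+),
serum-free control (-/-), and a serum gradient (-/+) in which cells are
given a directional drift.  The classifier requires directionality
(Rayleigh tests) only in the gradient arm plus the forward-migration-
index pattern before calling the cohort chemotactic.
"""

from paccquant import MigrationSimConfig, build_report, classify_chemotaxis, simulate_trajectories

biases = {"+/+": 0.0, "-/-": 0.0, "-/+": 0.4}
reports = {}
for i, (label, bias) in enumerate(sorted(biases.items())):
    cfg = MigrationSimConfig(n_cells=60, drift_bias=bias, persistence=0.3, seed=10 + i)
    tset = simulate_trajectories(cfg, condition_label=label)
    reports[label] = build_report(tset, seed=100 + i)

for label in ("+/+", "-/-", "-/+"):
    r = reports[label]
    print(
        f"{label}: Rayleigh p={r.rayleigh_p:9.3g}  vector p={r.rayleigh_vector_p:9.3g}  "
        f"FMI par={r.fmi_parallel:+.3f}  FMI perp={r.fmi_perpendicular:+.3f}"
    )

result = classify_chemotaxis(reports)
print(f"\nchemotactic verdict: {result.verdict}")
for name, passed in result.criteria.items():
    print(f"  {name}: {'pass' if passed else 'FAIL'}")
print(
    "\nOnly the gradient arm is directional (tiny Rayleigh p, positive parallel\n"
    "FMI); the controls have near-zero FMIs. Control significance is judged\n"
    "family-wise (Bonferroni over the four control p-values), so one control\n"
    "p-value slightly under 0.05 - expected by chance in 4 tests - does not\n"
    "derail the verdict."
)
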