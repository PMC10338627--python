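"""Expression-side arithmetic: delta-delta-Ct fold change from a qPCR Ct
table, NanoString positive-control normalisation with the undetected
rule, and marker-positivity percentages from cell counts.
"""

import pandas as pd

from paccquant import (
    delta_delta_ct,
    nanostring_normalize,
    positivity_fraction,
    simulate_ct_table,
)

# --- qPCR: known 4-fold induction, 0.15-cycle technical noise ---------------
table = simulate_ct_table(fold_change_true=4.0, n_replicates=6, ct_noise_sd=0.15, seed=2)
res = delta_delta_ct(table)
print(f"ddCt fold change: recovered {res.fold_change_summary:.2f} (truth 4.0) "
      f"from {res.n_replicates} replicates, mean ddCt = {res.mean_ddct:+.3f}")

# --- NanoString: second sample loaded twice as heavily ----------------------
counts = pd.DataFrame(
    {"lane1": [1000, 500, 39, 210], "lane2": [2000, 1000, 95, 430]},
    index=["POS_A", "POS_B", "geneX", "geneY"],
)
norm = nanostring_normalize(counts, ["POS_A", "POS_B"])
print("\nNanoString scale factors:",
      {k: float(v) for k, v in norm.scale_factors.round(3).items()})
print("geneY normalised:",
      {k: float(v) for k, v in norm.normalized.loc["geneY"].round(1).items()},
      "(lane loading removed)")
print("geneX lane1 undetected (raw 39 < 40):", bool(norm.undetected.loc['geneX', 'lane1']))

# --- positivity from counted cells ------------------------------------------
for name, (pos, total) in {"PACC state": (120, 123), "parental": (286, 971)}.items():
    p = positivity_fraction(pos, total)
    print(f"{name}: {p.n_positive}/{p.n_total} marker-positive = {p.percent_rounded}%")
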