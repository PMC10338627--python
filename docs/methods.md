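# Methods

`paccquant` quantifies the phenotypes that distinguish polyaneuploid
cancer cells (PACCs, the enlarged, polyploid, therapy-surviving cell
state) from their parental populations: single-cell motility, directed
chemotaxis, cytoskeletal dynamics and stiffness, and a set of small
expression-side calculations.  This note records the models, estimators,
numerical choices, and what the synthetic data do and do not emulate.

## Trajectory metrics

A trajectory is one cell's time-ordered 2D positions (minutes, µm) from
time-lapse imaging.  Metrics are purely geometric and never assume
uniform sampling:

* **accumulated distance** `L = Σᵢ |rᵢ₊₁ − rᵢ|` — total path length;
* **Euclidean distance** `d = |r_N − r_1|` — net displacement;
* **directness** `d/L ∈ [0, 1]`, 1 for a perfectly straight path.

A cell that never moved has `L = 0`; its directness is 0/0 and is
reported as missing (NaN) and excluded from cohort summaries — never
coerced to 0 or 1.  Cohort summaries are per-cell (one number per cell),
matching dot-plot reporting conventions, not per-step pooling.

Cells flagged as having divided, apoptosed, or left the field of view
are removed before any cohort statistic; removals are logged so the
reported n per condition stays auditable.  Metric-versus-area relations
are ordinary least squares (`scipy.stats.linregress`) on cells that have
both an area annotation and a defined metric; constant areas are a
degenerate-regressor error rather than a silent `R² = 0`.

Coordinates are Cartesian (+y up) after import.  Readers flip
image-convention (+y down) inputs at the boundary so the declared
gradient axis means the same thing for every input dialect.

## Chemotaxis statistics

All directional statistics operate on the origin-translated endpoint of
each trajectory (the spider-plot endpoint).

**Rayleigh test.**  For endpoint angles θᵢ, the mean resultant length is
R̄ = |Σ e^{iθᵢ}|/n and Z = nR̄².  The p-value uses the standard
small-sample-corrected exponential approximation

    p ≈ exp(−Z)·[1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)]

clamped to [0, 1].  Measured type-I error at n = 50 over 10 000
replicates is ≈ 0.047–0.050 at α = 0.05.

**Rayleigh test for vector data.**  Moore's rank-based modification:
endpoint magnitudes are replaced by mid-ranks rᵢ (ties noted in the
result), and the statistic is R* = |Σ rᵢ·(cos θᵢ, sin θᵢ)| / n^{3/2}.
Under the null hypothesis of uniform directions the angles are
independent of the magnitude ranks, so the null law of R* depends only
on n; p-values come from a seeded Monte-Carlo sample of that null
(default 10 000 draws; a precomputed null table can be shared across
tests of equal n).  Note that permuting ranks against the *observed*
angles would test magnitude–angle independence, not uniformity — it
cannot reject even when every endpoint points the same way — so the
null is simulated with uniform angles instead.  Which vector-data
variant the original ImageJ tooling used is not documented anywhere we
could verify; Moore's test is the standard rank-weighted choice and the
exact procedure is recorded here so values are reproducible.

**Forward migration indices.**  Per cell, with unit gradient axis ĝ and
its +90° rotation ĝ⊥:

    FMI∥ = (endpoint · ĝ) / L,   FMI⊥ = (endpoint · ĝ⊥) / L.

The cohort index is the arithmetic mean over cells.  By construction
FMI∥² + FMI⊥² = directness² per cell (exactly, up to float rounding),
which the tests assert at 1e-9.  Cells with L = 0 are reported missing.

**Chemotaxis decision.**  A three-condition design: uniform serum
(+/+), serum-free (−/−), gradient (−/+).  The cohort is called
chemotactic iff

1. both Rayleigh variants are significant for the gradient arm at α and
   no control test is significant;
2. gradient FMI∥ is significantly higher than both control FMI∥s
   (one-sided Mann–Whitney on per-cell components at α);
3. gradient FMI∥ is significantly higher than gradient FMI⊥, and
   |gradient FMI⊥| ≤ ε;
4. all four control cohort FMIs satisfy |FMI| ≤ ε.

Design choices, made where the procedure was genuinely open:

* *Control significance is family-wise.*  Four control p-values (two
  tests × two control arms) are screened; judging each at raw α would
  spuriously derail the verdict in ~10–14% of truly chemotactic
  experiments purely by control false positives.  A control therefore
  counts as "significant" only below α/4 (Bonferroni over the control
  family; `control_adjust="none"` restores the raw-α behaviour).  This
  holds the probability that control noise blocks a true verdict at ≈ α.
* *"Significantly higher" is a one-sided Mann–Whitney* on per-cell FMI
  components, consistent with the nonparametric conventions used for
  every other cohort comparison.
* *"Close to zero" is ε = 0.1* of the dimensionless FMI by default,
  exposed as `near_zero_epsilon`; no published threshold exists.  At
  n = 60 cells the standard error of a null cohort FMI is ≈ 0.02, so
  ε = 0.1 is a lenient, conservative-against-false-negatives bound.
* α = 0.05 throughout, matching standard practice for these assays.

Measured operating characteristics (200 simulation replicates, 60
cells/arm, persistence 0.3): detection rate ≈ 0.97–0.99 at gradient
drift bias 0.4; false-call rate ≤ 0.01 with no bias anywhere.

**Group comparisons** are two-sided Mann–Whitney U (exact for small
tie-free samples, normal approximation otherwise — scipy's policy) and
Kruskal–Wallis for ≥ 3 groups.

## Biomechanics

**MSD.**  MSD(τ) averages |r(t+τ) − r(t)|² over all overlapping start
times within each bead and then over the bead ensemble, recording the
pair count per lag.  Overlapping time-averaging maximises the number of
pairs; for the stationary-increment processes simulated here, time- and
ensemble-averaged MSD coincide in expectation.  The diffusion
coefficient is slope/4 of a straight-line fit (intercept retained to
absorb static localisation noise); the anomalous exponent is the
log–log slope.

**MTC stiffness.**  Torque and displacement amplitudes at the driving
frequency are extracted by linear least squares on
{sin ωt, cos ωt, 1}; stiffness is their ratio (Pa/nm), invariant to the
viscoelastic phase lag by construction.  Requires ≥ 2 full periods.  A
displacement amplitude at or below the declared noise floor (the
instrument's optical resolution, ~5 nm) raises an unmeasurable-signal
error instead of returning an unbounded stiffness.

**Hertz fit.**  For a conical tip, F = k·E·δ² with
k = 2 tan α / (π(1 − ν²)), α the tip half-opening angle (stored in
degrees, converted at the boundary) and ν the Poisson ratio (0.5 for
incompressible soft material).  Because k is a known constant, E is the
coefficient of a one-regressor linear least-squares problem on δ² and is
solved in closed form, Ê = ΣFδ²/(kΣδ⁴) — the same optimum a nonlinear
fit would reach, without iteration.  Negative estimates under heavy
noise are clamped to 0 with a warning.  Points beyond a declared
maximum indentation (e.g. past the instrument's 1 nN force setpoint
region) can be excluded via `max_indentation`.

**Contact point.**  Raw approach curves are offset by fitting, for each
candidate contact position z₀, the piecewise model: constant baseline
before z₀ and baseline + c·(z − z₀)² (c ≥ 0) after, keeping the z₀ with
minimal total squared error.  If the fitted rise above baseline at full
approach is below 3× the baseline residual scatter, the curve is
flagged "no detectable contact" and excluded rather than fitted.

## Synthetic data

The generators reproduce each assay's acquisition geometry with known
ground truth, so every estimator is validated by parameter recovery.

**Migration (biased persistent random walk).**  Defaults: 49 frames at
30-min intervals (24 h).  At each frame the step direction is von Mises
around the direction of v = persistence·ĥ + drift_bias·ĝ (previous
heading ĥ, gradient ĝ), with concentration κ chosen by Best–Fisher
inversion so the noise's mean resultant length equals ‖v‖.  Hence:
‖v‖ = 0 gives a uniform direction; ‖v‖ ≥ 1 a deterministic step
(drift_bias = 1, persistence = 0 yields an exactly straight up-gradient
line); and with no drift, `persistence` is approximately the circular
correlation of successive headings.  Step lengths are
truncated-Gaussian (at zero): speed ~ N(mean, sd)·Δt.  Default speeds
(0.5 ± 0.2 µm/min) are *arbitrary documented defaults* at the scale of
slow epithelial migration — no per-cell speeds were ever published for
calibration.  Each cell consumes its own child RNG stream spawned from
the master seed, so enlarging the cohort never reshuffles earlier
cells, and every generator is bitwise-reproducible.

**Beads.**  Defaults: 100 beads, 12 frames/s, 300 s.  For anomalous
exponent a = 1, iid Gaussian increments with per-axis variance 2DΔt
(ensemble MSD = 4Dτ).  For a ≠ 1, exact fractional Gaussian noise with
Hurst index H = a/2 synthesised by Davies–Harte circulant embedding,
scaled so MSD(τ) = 4Dτ^a with stationary increments (so the
time-averaged estimator remains unbiased).

**Force curves.**  δ uniform on [0, max_indentation] (default 1 µm,
200 points), F from the Hertz relation plus optional Gaussian force
noise; α = 35°, ν = 0.5 defaults.

**Ct tables.**  Housekeeping Ct 18, target Ct 22 in the control
condition (typical abundances), target shifted by −log₂(fold) in the
treated condition, optional iid Gaussian cycle noise; the noiseless
table encodes ΔΔCt = −log₂(fold) exactly.

What the generators do **not** emulate: cell division/apoptosis
dynamics (exclusion flags are annotations, not simulated events),
cell–cell crowding or confinement in the chemotaxis chamber,
localisation/tracking error in positions, bead detachment and drift,
AFM cantilever hydrodynamics and adhesion forces, and qPCR efficiency
deviations from the ideal doubling assumed by 2^(−ΔΔCt).  Passing
recovery tests therefore demonstrate estimator correctness under the
stated models, not robustness to every artefact of real recordings.

## Expression calculations

ΔΔCt: ΔCt = Ct_target − Ct_housekeeping per condition,
ΔΔCt = ΔCt_treated − ΔCt_control, fold = 2^(−ΔΔCt).  The replicate
summary is 2^(−mean ΔΔCt) — the geometric mean of replicate folds, the
natural scale for log-linear Ct data; per-replicate folds are also
returned.  Incomplete replicates are excluded with a warning.

NanoString: raw counts < 40 are flagged undetected *before* scaling
(the rule is stated on transcript reads, i.e. raw counts); each sample
is then scaled by (mean positive-control total)/(its own total), which
preserves within-sample ratios.  Zero-control-total samples are
excluded with an error record.

IntDen is the pixel-intensity sum over a segmented cell, MFI the
per-pixel mean; MFI × pixel count ≡ IntDen.  Exposure time is carried
as metadata and never used to rescale across exposures (different
exposures are not directly comparable).  Positivity percentages are
reported exact and rounded; the threshold for calling a cell positive
is an input, not inferred.  Anoikis resistance and densitometry are
guarded ratios (positive denominators required), with optional
background subtraction and reference-lane normalisation.

## Problem sizes and tolerances

Recovery checks run at sizes where Monte-Carlo error is far below the
asserted tolerance while the whole suite stays interactive: 1000 cells
for metric identities, 1000 beads × 30 s at 12 fps for D recovery
(within 10%), 1000 noisy force-curve replicates (mean Ê within 2%),
10 000/5 000 replicates for Rayleigh/vector-test calibration (rate in
[0.04, 0.06]), 200 replicates for classifier operating characteristics.
Float comparisons against closed forms use 1e-9 relative tolerance;
identity checks (FMI vs directness, MFI vs IntDen) use 1e-9–1e-12
absolute.  `scripts/acceptance.py` recomputes all of these from scratch
with a caller-supplied seed.

## Known limitations

* The walk model is a single-mode biased persistent random walk; it does
  not reproduce mode-switching (amoeboid/mesenchymal) or heavy-tailed
  step distributions seen in some cell types.
* Moore's test p-values are Monte-Carlo and therefore carry simulation
  granularity of ~1/n_reps; calibration tests share a null table across
  replicates, which introduces (negligible at 20 000 draws) dependence.
* The Hertz model assumes a rigid conical indenter on a flat
  semi-infinite incompressible sample; thin-sample and adhesion
  corrections are out of scope.
* MTC stiffness is reported at the driving frequency only; no
  frequency-dependent (viscoelastic) modulus is estimated.
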