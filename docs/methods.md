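# Methods

## Flow model

The vessel segment is idealized as a 2D plane channel: walls at
y = −0.02 m and y = −0.01 m, axial extent x ∈ [−0.14, 0.08] m, so the gap
is 1 cm and the centerline sits at y = −0.015 m.  Blood is treated as a
Newtonian fluid (ρ = 1050 kg/m³, μ = 3.5 mPa·s — whole-blood values).  The
inlet carries the parabolic profile
u(y) = u_peak (1 − ((y − y_c)/h)²) modulated by a heartbeat factor
1 + A sin(2πft) with A = 0.2 and f = 1.2 Hz (72 bpm).  The study computes
a single phase snapshot rather than a transient cycle; the default phase
is the systolic peak, where the time factor is 1.2 and the effective
centerline speed is u_peak · 1.2 = 0.5 m/s.  The gap Reynolds number is
ρ·0.5·0.01/μ = 1500, laminar for a plane channel.

The suspended nanocarriers are not resolved: the fluid is a dilute,
linearly magnetizable continuum with susceptibility χ (default 0.05).  The
external permanent magnet is a point dipole (moment 5·10⁻⁴ A·m², pointing
+y) placed 7.5 mm below the lower wall; its field uses the point-dipole
expression evaluated in the flow plane, decaying as 1/r³.  The magnetic
body force is the Kelvin form F = μ₀ χ (H·∇)H.

**A consequence worth stating plainly:** for a curl-free magnetostatic
field, (H·∇)H = ∇(|H|²/2), so with spatially uniform χ the Kelvin force is
irrotational and is absorbed entirely by the pressure field of an
incompressible flow.  The magnet therefore imprints on the pressure, not
on the velocity: the exported velocity field is Poiseuille-like to within
solver tolerance at any magnet strength.  Capturing a velocity-visible
magnetic effect would require concentration gradients of the carriers
(two-phase or drift-flux modelling), which is out of scope here.  The
dataset statistics this package targets (peak ≈ 0.5 m/s, zero wall
velocity, mean ≈ ⅔ of peak) are properties of the channel flow itself and
are insensitive to this.

## Numerics

The steady state is reached by pseudo-time marching a staggered-grid
(MAC) explicit projection scheme:

- first-order upwind advection, centered diffusion (both exact for the
  parallel Poiseuille solution, whose discrete error comes only from the
  O(Δy²) wall-ghost reflection);
- Dirichlet inlet, Neumann outflow with an exact global mass-balance
  correction each step;
- a pressure Poisson solve with homogeneous Neumann boundaries, one cell
  pinned, factorized once (`scipy.sparse.linalg.splu`), which drives the
  discrete divergence to round-off (~10⁻¹¹ s⁻¹ against a 10⁻⁶ contract);
- time step 0.4 × the tightest of the advective and diffusive limits.

Convergence is declared when the maximum acceleration max|Δu|/Δt falls
below `steady_tol · u_max²/L` (default `steady_tol` = 10⁻⁴; ≈ 1.1·10⁻⁴
m/s² at the default scales).  The tolerance sits well below the magnetic
force scale (|F|/ρ ≈ 8·10⁻⁴ m/s²) so any force-driven transient is
resolved rather than truncated.  Non-convergence and super-critical
Reynolds numbers (> 4000) raise errors naming the offending quantity.
The march starts from the Poiseuille profile by default (`init="rest"`
reproduces the full startup transient and is used in the validation
tests).

The exported table holds one row per grid node (425 × 41 = 17,425 ≥
17,000), with face velocities averaged to nodes, wall rows exactly zero,
and U = √(u² + v²).  On a uniform node lattice the mean of the parabolic
profile is ≈ 0.325·u_max (the lattice analogue of ⅔·u_peak·1.2·(1−ε)),
about 4% below the reference value 0.338 obtained on a non-uniform FEM
mesh — within the 5% band the study targets; the node-interpolated peak is
0.49969 m/s, 0.07% below the reference 0.500050.

## Preprocessing

- **Isolation forest** (100 trees, subsample ψ = 256, seeded) scores each
  row with the canonical s = 2^(−E[h]/c(ψ)), c(n) = 2H(n−1) − 2(n−1)/n;
  scoring is delegated to scikit-learn (whose `score_samples` is the
  negated canonical score).  Rows above `score_threshold` are dropped.
  The default threshold 0.6 trims ~6% of rows — those near walls and
  corners of the rectangular domain, where any finite sample looks
  locally sparse.  Empirically the boundary inliers of *any* 2-D cluster
  score 0.60–0.67 under this normalization, so 0.6 is an aggressive
  screen; 0.7 cleanly separates genuinely planted outliers (tests pin
  this behaviour).  The threshold is config-visible, not hard-coded.
- **Min–max scaling** maps x, y and U to [0, 1]; parameters are fitted on
  the training split only and applied to test (no leakage).  Metrics are
  computed after inverse-transforming predictions back to m/s, which is
  what makes RMSE = sd(y_test)·√(1 − R²) hold on the test sample.
- **Split**: seeded uniform permutation, first ⌊0.8 n⌋ rows to train.

## Surrogates

AdaBoost.R2 with linear loss, written here rather than taken from a
library because both aggregation rules are needed: per round t the base
model is fitted to the weighted sample (trees receive weights natively;
KNN and MLP are fitted on a weighted bootstrap), per-row losses are
normalized by the round's maximum error, the average loss L̄ₜ sets
βₜ = L̄ₜ/(1 − L̄ₜ) and the model weight ln(1/βₜ), and weights update as
wᵢ ← wᵢ βₜ^(1−lᵢ).  Rounds stop early when L̄ₜ ≥ 0.5 (model discarded) or
when a round fits essentially perfectly (kept with a capped weight).  On
the smooth channel dataset the depth-8 tree ensemble typically saturates
after ~10 rounds; the configured 450 is a cap, not a quota.  Default
aggregation is the confidence-weighted average; the weighted median is a
config switch, and a test cross-checks the median variant against
scikit-learn's AdaBoost regressor on independent data.

Base learners delegate training to scikit-learn: CART with
variance-reduction splitting (regression has no entropy/Gini notion) and
seeded tie-breaking — the node grid has many tied split candidates, so an
unseeded tree is not reproducible; KNN with true Euclidean distance
(k = 2 default); an MLP with hidden layers (66, 29), ReLU, trained by
L-BFGS on the MSE (full-batch quasi-Newton is fast and deterministic at
this parameter count; ~2,200 weights).  The MLP ensemble uses 20 rounds
by default (12 in the acceptance script) instead of the tuned 180: each
L-BFGS fit costs seconds, and the ensemble's test error stabilizes well
within a dozen rounds on this dataset.

## BAT tuner

The swarm moves by the three printed rules (frequency, velocity,
position), with positions clipped to bounds, integer dimensions rounded
after every move, and velocities clamped to one box width.  The bare
three-rule recursion is linearly *unstable* around the best position
(eigenvalues of the (v, Θ−Θ*) map exceed 1 for every frequency), so on
its own it only explores during the initialization transient; measured on
a 2-D sphere objective it lands within 0.5 of the optimum in only 1 of 10
seeds.  The classical loudness/pulse-rate mechanics — a small random walk
around the best with probability 1 − r, acceptance of worse moves with
probability A — restore exploitation and give 10/10 convergence, so they
are enabled by default (`use_loudness=False` recovers the bare variant).
The CV objective is k-fold R² (default 3 folds), seeded, with failed fits
scored −∞.  Hyperparameter tuples (hidden layer sizes) are flattened into
integer dimensions and regrouped on decode.  The tuned values the study
ships as defaults (K = 2, depth 8, (66, 29), 10/180/450 estimators) are
frozen in `TUNED_HYPERPARAMS`, so default runs do not re-tune.

## What the generator does and does not emulate

The simulated dataset reproduces the reference geometry, row count, value
ranges and the wall/centerline structure of the velocity field, on a
uniform lattice.  It does **not** reproduce: the unknown magnet/vessel
geometry of the original apparatus (replaced by the configurable dipole),
non-uniform FEM node placement (visible as a slightly different mean and
standard deviation of U), non-Newtonian rheology, elastic walls, 3D
effects, or transient heartbeat sweeps.  Surrogate metrics computed here
therefore certify the method on an *equivalent* simulation, not bit-level
replication of the original dataset.

## Problem sizes and tolerances used in the shipped runs

- Flow: 425 × 41 nodes (default), ~2,500 pseudo-time steps, ~30 s.
  Validation tests use 49 × 25 and 25 × 13 unit-scale channels.
- Surrogates: 13,032 training / 3,258 test rows after screening; tree cap
  450 rounds, KNN 10, MLP 12–20.
- Learning curve: 15–30 boosting rounds, sizes up to 9,000, 3 folds.
- Tuner demonstrations: ≤ 20 bats × ≤ 50 iterations.

## Known limitations

- The magnetic force cannot alter the velocity of this single-phase model
  (see above); velocity-coupled magnetic effects need a concentration
  field.
- The explicit solver's time step scales with Δy², so grids much finer
  than the default become slow; an implicit diffusion step would lift
  this.
- AdaBoost.R2's loss normalization makes early stopping sensitive to a
  single hard row; the 0.5 average-loss stop is canonical but means the
  configured estimator count is an upper bound.
- Isolation-forest screening on a regular lattice removes boundary rows
  rather than "outliers" in any physical sense; it is kept because the
  study's cleansing chain includes it, and it is harmless to the
  surrogates.
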