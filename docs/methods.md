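# Methods

## Model

Scanpaths are discretized by 5-state partitions of the display. Geometry
conventions: origin top-left, y downward, all region intervals half-open
`[lo, hi)`, so every point of the plane maps to exactly one state. The
border (state 5) is the margin of width `border_fraction` (default 0.10)
of the display extent on each side; its area fraction is exactly
`1 − (1 − 2·bf)²`. Vertical states are numbered top → bottom, horizontal
left → right, radiating center → periphery; the radiating rings are
concentric rectangles matching the display aspect ratio, with boundaries
at fractions 1/4, 2/4, 3/4, 4/4 of the inner half-extent (the simplest
construction consistent with "radiating from the center", since nothing
pins down the exact ring geometry). Off-display coordinates (tracker
noise) map to the border state rather than erroring.

The successor representation of a trial is learned online: `M ← 0`, then
for each transition `i → j`, column update
`M_i += α(e_j + γ·M_j − M_i)`, reading the *current* matrix at every step
(standard TD(0); no eligibility traces, no carry-over between trials).
Self-transitions are ordinary updates — dwell time in a state is part of
the signal. Parameter bounds are `0 < α ≤ 1`, `0 ≤ γ ≤ 1`; the closed
upper bounds are admitted deliberately because grid searches legitimately
select boundary values (γ = 1 merely disables discounting for a finite
sequence). The analytic fixed point `M* = T(I − γT)⁻¹` (columns sum to
`1/(1−γ)`) requires γ < 1 and serves as an independent oracle: a 2×10⁵-step
simulated chain learned at α = 0.005 matches it to max-abs error < 0.05.

Prediction: participant mean SRs (25-vectors) → mean-centering → PCA to 5
components → OLS with intercept. R² and Rcv² are *squared Pearson
correlations* of fitted/held-out predictions against observations (the
`1 − SSE/SST` form is also computed and stored on the CV result, but the
correlation form is the canonical output). In leave-one-out CV the
centering, PCA, and regression are all refit on each training fold, so no
statistic of the held-out participant leaks into their fold's model; the
per-fold weight matrices are averaged into the mean prediction weights
used for interpretation. Grid search maximizes Rcv² (not R², which is
optimistic), breaking ties toward smaller γ then smaller α — the least
temporally extended model at equal fit. The intercept is a score offset
only; it does not enter the weight matrix.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `border_fraction` | 0.10 /side | width of border state 5 (unitless fraction) |
| `α` grid | 0.01, 0.05 … 1.00 | TD learning rate (two-decimal grid; CLI default is a coarser 0.2-step grid for speed) |
| `γ` grid | 0.01, 0.05 … 1.00 | temporal discount |
| `n_components` | 5 | principal components kept |
| `signal_threshold` | 75% | minimum mean per-trial tracking signal |
| `px_per_degree` | 1024/29 ≈ 35.3 | display geometry scale for saccade amplitude |
| `interpret_k` | 10 | extreme-group size |

## Preprocessing

Participants are excluded when their mean per-trial signal percentage
falls below threshold; the first fixation of each trial (forced central
pretrial fixation) is removed and orders renumbered. Traditional metrics
use per-trial means first, then mean and sample SD (n−1) across trials;
saccade amplitude is the inter-fixation Euclidean distance in degrees
(fixation events, not tracker saccade events, are the data model).

## Synthetic cohorts

The generator emulates the study-scale data shape: 40 participants × 40
trials, Poisson(36) fixations per trial (min 2), 1024×768 display,
lognormal durations (σ = 0.4, mean ≈ 281 ms), central first fixation,
per-trial signal percentages (dropout participants drawn in 40–70%,
others 85–99%). A latent trait z ~ N(0,1) maps affinely onto each
questionnaire's printed scale (attention-deficit 0–96, mean 45, SD 15;
autism quotient 0–50, mean 18, SD 6; dyslexia 0–20, mean 7, SD 3.5),
rounded to integers — mild right-asymmetry arises from clipping, but the
exact empirical score distributions of any particular cohort are not
reproduced. All three measures derive from the same z, so synthetic
measures are mutually correlated by construction.

*First-order effect:* the sender-conditional law interpolates
`T(z) = (1−w)·T_low + w·T_high`, `w = effect_size·Φ(z)`. `T_low` makes
broad vertical excursions; `T_high` pulls toward the central bands with a
deliberate 2-over-3 asymmetry, because bands 2 and 3 are mirror images
about the display center and the radiating geometry cannot distinguish
them — this is what makes the planted structure specifically *vertical*.

*Second-order effect:* all participants share one first-order law
`T0 = (T_low+T_high)/2`; the trait enters only through
`P(r | j, k) = T0[r,j]·(1 + c·(1[r=k] − T0[k,j] − π0(r|j) + m_j))`,
a signed tendency (`c = effect_size·(2Φ(z)−1)`) to return to (c > 0) or
avoid (c < 0) the state visited two steps back. The correction terms make
the kernel average back to `T0` under the base chain's reverse kernel
π0, leaving an O(c²) residual that is even in c and therefore essentially
uncorrelated with the trait. Only temporally extended statistics carry
signal, which is exactly the regime where the SR should beat first-order
transition frequencies — and does, in ≥ 8/10 seeded replicates.

What the generator does **not** emulate: scene content and semantics,
saliency, inter-scene heterogeneity (all scenes share one law unless
`effect_trials` restricts the effect), measurement error in scores beyond
rounding, per-participant calibration error, and fixation-duration/
position dependence. Passing recovery tests therefore shows the pipeline
recovers the *kind* of structure it assumes, at realistic scale and noise
— not that real viewing data contains such structure.

## Numerical choices and degenerate inputs

- Half-open boundary convention everywhere; a point on a shared edge
  belongs to the higher-index region's lower edge.
- Zero-transition trials give exactly zero SR / transition matrices;
  their correlation with weights is undefined and excluded from
  interpretation aggregation (flat group differences warn and return the
  first scene deterministically).
- Constant scores give exactly zero regression slopes and a zero weight
  matrix; correlation-based R² is defined as 0 when either side is
  constant.
- Rank-deficient SR designs (fewer distinct patterns than components)
  raise a degenerate-fit error; collinear traditional metrics warn and
  fall back to the pseudo-inverse.
- Extreme-group and tie situations resolve by participant-id order, and
  grid-search ties by (γ, α) ascending — all outputs are deterministic
  given inputs and seed.
- The estimator needs n ≥ n_components + 1 samples (the mathematical
  minimum); the user-facing fit asks for one more; leave-one-out needs
  n ≥ 7.

## Problem sizes used in checks

Recovery and null simulations run at the default cohort scale (40 × 40 ×
~36) with a 3 × 3 (α, γ) grid (α ∈ {0.3, 0.7, 1.0}, γ ∈ {0.1, 0.5, 0.9})
over 10 seeds; the permutation null uses 20 shuffles; the planted-scene
interpretation check uses 4 scenes of ~60 fixations with the effect
confined to one scene, a design with enough per-scene signal for the
selection to be stable. The fine two-decimal grid remains available for
full analyses via configuration.

## Known limitations

- The SR fixed-point oracle does not exist at γ = 1; learned SRs there
  are finite-sequence objects only.
- Rcv² as a squared correlation is insensitive to calibration (a model
  predicting a·y + b scores perfectly); the SSE-based variant is exposed
  on `CVResult.rcv_squared_sse` for calibration-sensitive use.
- Grid search selects on the same LOO folds it reports, so the maximum
  over the grid is itself mildly optimistic; a fully unbiased estimate
  would need nested CV, which is out of scope here as in common practice.
- With 5 states and 5 components the PCA step discards little variance;
  its role grows with finer state spaces.
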