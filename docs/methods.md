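# Methods

This note documents the models and numerical choices behind kinemorph: the
stimulus machinery (standardization, expansiveness, morphing), the session
protocol, the synthetic-data generators, and the statistical analysis.

## Coordinate convention and the skeleton

Coordinates are pixels with the origin at the screen's lower left and *y
increasing upward*, so vertical amplitudes grow as the hands rise. The desk
is a horizontal reference line `desk_y` below the resting hands; it scales
and translates with the figure during standardization.

The canonical landmark set has 12 names: forehead, throat, left/right
shoulder, left/right elbow, left/right hand, left/right hip, centre of
gravity, sternum. Only five of them (forehead, throat, both hands, centre
of gravity) enter any measurement; the rest exist so a rendered figure has
limbs and so morphing acts on a full body. The set is a package convention:
any 12 unique names containing the five measured landmarks are accepted.

## Standardization

Body height and limb length differ between recorded speakers and would
confound amplitude measures. Each sequence is therefore

1. **uniformly scaled** about the coordinate origin by
   `275 / max_t |y_forehead,t − y_cog,t|`, bringing the maximal
   forehead-to-centre-of-gravity stretch to the standard 275 px. The same
   factor applies to x and y, so shape and amplitude ratios are preserved;
2. **rigidly translated** so the centre of gravity in the maximum-stretch
   frame lands on the anchor (345, 341).

"Maximum stretch" ties break to the earliest frame. The composition is
idempotent to ~1e-9 (floating-point only). A figure whose forehead and
centre of gravity coincide in every frame has no defined scale and is
rejected.

## Expansiveness and window selection

Per frame, vertical expansiveness sums the heights of the two hands and the
throat above the desk line; horizontal expansiveness sums the horizontal
offsets of the hands from the throat plus the throat's offset from the
coordinate origin (body sway). Both are nonnegative by construction.

A figure's most expansive episode is the contiguous window of 5 s × fps
frames (125 at 25 fps) maximizing the *summed* per-frame score, found by a
cumulative-sum sliding window with stride 1; ties take the earliest start.
The windowed sum rather than the peak value was chosen because it rewards
sustained expansive movement; the alternative (peak per-frame score) ranks
almost identically on smooth motion but is noise-sensitive. Top-k selection
across a catalog is a stable descending sort on window score, so equal
scores keep catalog order and the selection is deterministic.

Per-landmark (max − min) amplitudes within the chosen window are reported
for plausibility checks only; they play no role in selection.

## Prototypes and morphing

A **prototype** moves along one axis only: vertical prototypes have every
frame's x-coordinates replaced by those of a static *standard figure*, and
vice versa. The standard figure is a neutral posture centered over the
desk with the hands held close together at navel height; its exact
coordinates (documented in `kinemorph.morph`) are a package convention
chosen to be consistent with a standardized figure (275 px stretch, centre
of gravity at the anchor, desk at y = 400).

A stimulus composes one vertical and one horizontal prototype under three
integer sliders s_v, s_h, s_vel ∈ {0..10}:

- per landmark i and frame t,
  `y'_{i,t} = w_v y_{i,t} + (1 − w_v) ȳ_i` with `w_v = s_v/10`, and
  symmetrically for x with `w_h`;
- playback rate `fps(s_vel) = round(25 + s_vel · 33/10)`, rounding half
  away from zero, i.e. 25 fps at the far left and 58 fps at the far right,
  42 fps at the center.

The fps map honors both printed endpoints by linear interpolation. An
11-position slider cannot reach 58 from 25 in constant 3-fps steps; the
linear map was chosen because the endpoints anchor the design (an original
implementation with 12 positions would explain the stated step size, but
the slider range 0..10 is explicit).

Composition is pure (same inputs → identical output). Prototype pairs of
unequal length — impossible with the 5-s windows the selection stage
produces, but possible with user data — are truncated to the shorter
length with a warning.

Interpolation is exactly linear in the weight, the vertical slider never
touches x-coordinates (and vice versa), and the velocity slider changes
only fps. Vertical expansiveness of the composed stimulus is non-decreasing
in s_v whenever the vertical prototype's hands/throat sit at or above the
standard posture — true for the expansive high-rankers the selection stage
produces. For a prototype *less* expansive than the resting posture,
damping toward the standard rightly increases expansiveness; the
monotonicity is a property of the study's stimuli, not of arbitrary input.

Animations export as GIF on a 768 × 432 canvas (stick mode draws the limb
segments, dot mode a single disc). GIF quantizes frame durations to 10 ms,
so the exact fps is also written to a JSON sidecar manifest.

## Session protocol

A session is ten rounds — five categories (dominant, trustworthy, friendly,
aggressive, competent) in a high and a low version — in a seeded uniform
random order. Each round independently draws one vertical and one
horizontal prototype uniformly from the 10 × 10 pools (100 equally likely
pairings) and starts all sliders at the center (5, 5, 5). A round can be
finalized only after all three sliders have been *touched*; touching with
the unchanged center value counts, because the unlock rule is about
interaction and forbidding the center value would bias responses. The
final record codes the high version as 1 and the low version as 0.
Session construction is a pure function of (items, pools, seed).

## Synthetic data

**Gestures.** A synthetic speaker is the standard posture plus sinusoidal
limb oscillation: hands carry the full amplitude with limb-specific
frequency (defaults ~0.2–0.6 Hz, the tempo of speech-accompanying
gestures) and phase, elbows follow at half amplitude, the upper body sways
gently. Smoothed Gaussian jitter (relative scale 0.02) roughens the pure
sinusoids. After composition the motion of each axis is rescaled so the
realized right-hand (max − min) amplitude equals the requested one exactly;
a requested amplitude of 0 freezes the axis. Corpus defaults draw
horizontal amplitudes from 90–250 px and vertical from 130–210 px, the
plausible right-hand ranges for lectern speakers; sequences default to
15 s at 25 fps. Everything is deterministic per seed.

What the generator does *not* emulate: discrete gesture strokes and holds,
hand-shape detail, posture shifts, or correlation between a speaker's
vertical and horizontal style. Passing selection/morphing tests on this
corpus therefore shows the machinery is correct, not that real gesture
corpora would yield the same prototype rankings.

**Responses.** A simulated participant population is a map from
(category, polarity) to target medians (m_h, m_v, m_vel) on the 0–10 scale
plus a dispersion σ. Each slider draws independently as
`clip(round(Normal(m, σ)), 0, 10)`. The default medians are the published
descriptive tables of the stick-figure and dot experiments. The default
σ = 3.0 was calibrated once against the published quartiles: the mean
absolute error between model and printed interquartile ranges plateaus
from σ ≈ 2.5–3 (clipping at the scale ends dominates beyond that), and
σ = 3 sits on that plateau. The true dispersion shape is unknown (only
quartiles are printed); the rounded Gaussian is a declared convention.
An optional Gaussian-copula mode adds latent inter-slider correlation for
stress-testing multicollinearity handling; by default the strong observed
correlations between cues emerge from the high/low contrast alone.

Because noise is independent per round with no participant-level
heterogeneity, simulated contrasts are *cleaner* than human data: at the
published aggressiveness medians (10 vs 2 on velocity) the high and low
responses can fail to overlap in a 42-participant sample, in which case
the logistic likelihood has no maximum and the analysis refuses the fit
(see below). This is the expected behaviour of the generative model, not a
defect of the analysis.

## Statistical analysis

**Descriptives.** Medians and quartiles per (category, polarity, slider),
using linear interpolation between order statistics (the numpy default;
the published tables do not state a quantile rule).

**Logistic regressions.** Maximum-likelihood fits of polarity on slider
values (multi-predictor and three single-predictor models per category),
via statsmodels. 95% CIs are **profile likelihood** — solving
`2[ℓ(β̂) − ℓ_p(β)] = χ²₁(0.95)` by offset-refits and Brent root finding —
matching the asymmetric intervals of the original analyses (R's
`confint.glm`); agreement with R is ~1e-4 on a fixture. Wald is the
fallback (with a warning) if profiling fails; p-values are two-sided Wald.
Complete or quasi-complete separation raises an explicit error rather than
returning a divergent fit (detected via the optimizer's separation
diagnostics plus a coefficient-magnitude guard of 30 on the standardized
scale). Constant predictors raise a rank error. Repeated-measures
dependence (each participant contributes one high and one low record per
category) is deliberately ignored, matching the original analysis; per
category n = 2 × participants.

**Relative importance weights.** For standardized predictors X with SVD
X = PΔQᵀ, the best orthogonal approximation is Z = PQᵀ and the loadings
are Λ = QΔQᵀ/√(n−1) (λ_jk = corr(x_j, z_k)). The outcome is regressed on
Z — OLS for continuous outcomes, logistic for binary — and the weight of
predictor j is ε_j = Σ_k λ²_jk β*²_k with standardized surrogate
coefficients β*. Weights are nonnegative, invariant to predictor order,
and sum exactly to R² in the linear case. In the logistic case the
weights are rescaled so their sum equals a **pseudo-R² analog**, by
default the squared Pearson correlation between the outcome and the
fitted probabilities (McFadden's ratio is available as an alternative);
the analog's name is carried in all outputs. The squared-correlation
analog was chosen because it behaves like an explained-variance fraction
summable across predictors; the published tables treat "explained
variance" as exactly such a scalar without naming a definition.

**Multiplicity and interval reading.** p-values are Bonferroni-controlled
over the family of 30 tests per experiment (5 categories × 3 predictors ×
2 model families; adjusted α = 0.05/30 ≈ 0.00167). Differences between
estimates are read from CI overlap: intervals that touch or are disjoint
correspond to roughly p < .01 (Cumming & Finch guideline); overlapping
intervals support no claim.

**Reports.** `build_report` emits the descriptives table, the
multi-predictor table (estimates, SEs, profile CIs, relative weights,
R² column — equal to the summed weights by construction) and the
single-predictor table, as a JSON-serializable dict plus aligned text.
A category whose multi-predictor fit separates keeps its single-predictor
rows; models that cannot be fit are omitted with a warning.

## Problem sizes and defaults

The demo pipeline defaults to a 100-sequence corpus of 15-s gestures at
25 fps, pools of k = 10 prototypes per axis, 42 simulated stick-figure and
40 dot participants, and a family size of 30 — the design of the study the
toolkit models. Simulation-based test suites use 100-replicate Monte Carlo
runs at those sample sizes, which keeps the full test suite under a
minute on one core while leaving the sign-recovery checks far from their
thresholds.

## Known limitations

- The 12-landmark set and the standard figure's exact coordinates are
  conventions; original landmark charts were never published.
- The response model has no participant random effects, no slider-order
  effects and no adjustment dynamics; it reproduces central tendencies and
  sign patterns, not full responses distributions.
- Profile CIs require refitting per bound; on separable data no CI exists
  and the fit is refused outright.
- Rendering is headless file export only; there is no interactive GUI.
- 3D motion, video decoding and automatic pose estimation are out of
  scope.
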