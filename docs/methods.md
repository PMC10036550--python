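# Methods

This note documents the models, conventions and numeric choices behind
wgskit: what is computed, under which assumptions, and which defaults are
anchored in the scale itself versus chosen as engineering defaults.

## The rubric and the weighted total

The 14-item paediatric WGS is encoded as a static table
(`wgskit.rubric`): per item an ordered list of options, each with a code
(`1`, `2a`, …), a numeric score equal to the code's leading digit, and
the behavioural anchor text. Items 4 and 11 carry *a/b* variants of
scores 2 and 3; the letter qualifies the deviation pattern and never
changes the numeric score, so swapping `2a`↔`2b` (or `3a`↔`3b`) leaves
the total invariant — a property the tests enforce.

The total is `Σ wᵢ·sᵢ` with weights 3/5 (item 1), 3/4 (item 11) and 1
elsewhere. Totals are kept as exact `fractions.Fraction` values; the
achievable range is [13.35, 42]. The scale's source material does not
state a rounding convention for display, so exports round **half-up to
two decimals**, matching the two-decimal presentation customary for this
instrument. An assessment without a declared affected side is scored but
flagged `unspecified` in exports, since every item is phrased relative to
the affected leg.

## Landmark geometry

Inputs are per-frame named 2-D landmarks (pixels), gait-event frame
indices (heel strike, toe off, mid swing, terminal swing per side —
annotated, never auto-detected), the frame rate, and a shoe-width pixel
calibration. Conventions, chosen because raw video pixels carry no
intrinsic frame:

- image origin top-left, y down; all angles are computed from vector
  differences with a well-conditioned atan2 form, so they are invariant
  under translation, rotation and uniform scaling (tested to 1e-9°);
- the progression direction is part of the calibration; sagittal views
  assume it is approximately horizontal;
- in frontal views the progression axis points towards the camera and is
  assigned the image direction (0, −1). Foot landmarks are treated as a
  ground-plane projection, so the heel→toe axis measured against that
  direction reads out foot rotation relative to the line of progression;
  lateral quantities (stance width, circumduction, trunk sway) use the
  frontal image x axis.

Item-level measurements:

- **Knee flexion (item 11)**: angle between the directed thigh line
  (trochanter → lateral femoral condyle) and shank line (fibula head →
  lateral malleolus); 0° = full extension. Peak flexion per side is taken
  over the pooled toe-off → mid-swing windows and classified in this
  order: affected knee at/below a 1° extension floor throughout swing →
  *none* (code 4); window peak below a 5° minimal-flexion floor →
  *minimal* (3a); above a 75° ceiling → *maximal* (3b); otherwise equal
  within tolerance (1), less (2a) or more (2b) than the unaffected peak.
- **Stance time (item 2)**: mean heel-strike → toe-off duration per side;
  the affected/unaffected ratio is *equal* at ≥ 0.9 and *very brief*
  below 0.5.
- **Stance width (item 5)** and **circumduction (item 9)**: lateral heel
  separation, and peak lateral swing deviation from the per-cycle stance
  line, in shoe widths. The rubric's "up to one / up to two shoe widths"
  anchors are inclusive boundaries (≤ 1, ≤ 2); circumduction below
  0.1 sw counts as none.
- **External rotation (item 8)**: unsigned heel→toe angle against the
  progression axis at an early-swing frame; "same as unimpaired" within
  5°, *marked* above the scale's 45° anchor.
- **Guardedness (item 6)**: duration, within the second half of affected
  stance, during which the hip's forward speed drops below 10 % of its
  series mean; > 0.1 s *slight*, > 0.3 s *marked* (engineering defaults —
  the scale gives no numbers).
- **Hip extension (item 7)**: thigh inclination from image vertical at
  toe off, extension positive; equal within 5°, *marked flexion* when the
  affected hip is flexed beyond 10°.
- **Hip hiking (item 10)**: pelvic obliquity (affected crest height over
  unaffected) at mid swing relative to its affected-stance baseline, in
  shoe widths; the side-difference form cancels the pelvis' shared
  vertical oscillation.
- **Toe clearance (item 12)**: per cycle, the stance-phase toe height
  defines the floor; the fraction of swing frames with clearance ≤ 1 px
  is the drag fraction (0 → normal, ≥ 0.5 → marked).
- **Step length (item 3)** and **trunk shift (item 4)**: forward advance
  of the unaffected toe past the affected toe/heel at unaffected heel
  strike; and the trunk midline's lateral position at affected
  mid-stance, expressed as a fraction of the midline-to-affected-foot
  distance (≥ 0.9 → full shift). The geometric evidence cannot separate
  the a/b variants of item 4; suggestions use the *a* form and leave the
  variant to the rater.
- **Initial contact (item 14)**: foot-axis pitch at the affected heel
  strike (heel-first ≥ +5°, toe-first ≤ −5°).

Item 1 (gait-aid use) is observational and always `manual`. Item 13
(pelvic rotation) is a transverse-plane quantity that single-plane
sagittal/frontal landmarks cannot resolve; the pipeline leaves it
`manual`, though `suggest_ratings` will classify a directly supplied
`pelvic_rotation_deg`. Every other missing measurement degrades that item
to `manual` rather than failing, and all thresholds above live in
`ThresholdConfig`, serialisable to JSON. Suggestions are advisory by
design — the stored rating is always the human rater's.

## Reliability statistics

- **ICC**: two-way random-effects, absolute agreement. The scale's
  validation convention names the model but not the formulas; the
  McGraw–Wong definitions are used: ICC(A,1) =
  (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)), ICC(A,k) =
  (MSR − MSE)/(MSR + (MSC − MSE)/n). Whether single- or average-measures
  was used originally is unstated; both are available and **single** is
  the default report column. A constant matrix raises an explicit
  undefined-ICC error (never a silent 0 or 1). Mean squares that are pure
  float dust relative to the dominant one are snapped to zero so exact
  agreement on fractional totals yields exactly 1.0; the average-measures
  form can exceed 1 when its denominator turns negative (between-subject
  variance swamped by rater variance) and that degenerate regime is
  labelled *poor*. Interpretation bands: poor < 0.40 ≤ fair < 0.60 ≤
  good < 0.75 ≤ excellent, boundaries belonging to the upper band.
  Confidence intervals for the ICC are deliberately out of scope.
- **Bland–Altman**: mean difference ± 1.96 SD (n−1) with the fraction of
  pairs inside the limits; zero-SD inputs give collapsed limits.
- **Kruskal–Wallis / Wilcoxon**: delegated to scipy.stats behind the
  module surface, with the degenerate conventions the report layouts
  need: all observations identical → H = 0, p = 1; all paired
  differences zero → p = 1.0 (classical zero-dropping). The exact
  Wilcoxon null is used for ≤ 25 untied non-zero pairs, the tie-corrected
  normal approximation otherwise.
- **Descriptives**: sample SD (n−1); quartiles by linear interpolation
  between order statistics (the convention is fixed and tested; the
  source material is silent).
- **Sample size**: Nmin = NP·α²f(1−f)/(NP·e² + α²f(1−f)), rounded up; α
  is the normal quantile (1.96-style), not a probability.
- **Multiplicity**: no correction is applied (none is conventional for
  these reliability layouts); the report carries `n_tests` so readers can
  judge the familywise context.

The JSON report is the canonical machine-readable artefact and
round-trips losslessly; the CSV tables are flat presentation views whose
cells are checked against the report in tests. "Excel export" is realised
as CSV.

## Synthetic data

**Panels** (`simulate_panel`): a latent true option per participant ×
item is drawn from a per-item distribution (defaults skewed towards the
milder half of each item, variants splitting their level's mass), then
each rater's rating is a symmetric ±1-category step with probability
`rater_noise` (clamped at scale ends; the variant letter is re-drawn
uniformly when a level has variants), and session-2 ratings re-perturb
the rater's session-1 rating with probability `session_drift`. Defaults
mirror the validation design — 31 participants, 3 raters, 2 sessions —
with `rater_noise = 0.05` and `session_drift = 0.02`, a high-agreement
regime consistent with the near-perfect test–retest pattern such panels
show in practice. The ±1-step model is the simplest defensible ordinal
error model; it cannot represent systematic rater bias or
item-correlated errors, so passing tests demonstrate statistical
correctness of the toolchain, not robustness to structured human error.

**Gait trials** (`simulate_gait`): a sagittal pelvis–thigh–shank chain
driven by sinusoidal hip and knee waveforms (stance knee bump 12°, swing
peak 60°, hip −10…+25°), feet following planted-stance/clearance-arc
trajectories, sampled at 30 fps over 1 s cycles with a 0.62 stance
fraction; segment lengths are standard anthropometric fractions of a
600 px stature and the shoe width is 0.055 × stature. A frontal
ground-plane projection carries the lateral quantities. Each deficit
(flexion-deficit fraction, circumduction sw, external rotation,
stance-time ratio, stance width, hip hiking, pause, toe drag, step mode,
contact mode, trunk-shift deficit) alters the affected side only and is
placed so the measurement layer recovers it within stated tolerances
(angles 1°, shoe widths 0.05, times 1 frame — rounding events to frames
is the only discretisation). Landmark groups are generated from their own
waveforms; full kinematic-chain consistency between the knee chain and
the foot is not enforced because no measurement couples them. Optional
i.i.d. Gaussian landmark noise models digitisation error; the generator
makes no claim to biomechanically realistic cerebral-palsy gait.

## Problem sizes in tests

The suite checks the ICC engine against a from-scratch ANOVA oracle on
1,000 random matrices (n ∈ 3–15, k ∈ 2–5) and against pingouin on a
subset; Bland–Altman coverage at n = 10,000; Wilcoxon against exhaustive
sign enumeration up to n = 10; Kruskal–Wallis against the tie-corrected
formula and a 10,000-resample permutation oracle; panel marginals at
5,000 subjects; ICC-vs-noise monotonicity over 200 replicates per noise
level; and planted-deficit recovery over 500 randomised noise-free
trials. These sizes give comfortable Monte-Carlo margins for every
threshold tested.

## Known limitations

- Single-plane geometry: pelvic rotation (item 13) and the a/b variant
  distinction of item 4 need information the annotation format does not
  carry; they remain with the rater.
- Events are trusted inputs; there is no landmark-based event detection
  or pose estimation, and no video decoding.
- The qualitative-item thresholds (pause, hip-hiking, equal-tolerances)
  are documented engineering defaults, not validated clinical cut-offs;
  clinics should calibrate `ThresholdConfig` before relying on
  suggestions.
- The ordinal noise model is exchangeable across raters and items;
  reliability results on synthetic panels therefore say nothing about
  rater-specific bias structure in real panels.
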