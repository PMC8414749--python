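# Methods

This note documents the models, conventions and numerical choices in
`scapkin`, in the order the pipeline applies them.

## Laboratory frame and segment reconstruction

All modules share one right-handed global frame (`scapkin.frame`):
+z opposes gravity, +x is the direction the seated subject faces, +y
points left. Marker coordinates are millimetres; every reported angle
is degrees.

Segments are reconstructed from the ten-marker set as follows. The
sternum longitudinal axis runs from the midpoint of (PX, T8) to the
midpoint of (IJ, C7), pointing cranially. The wrist point is the
radial/ulnar styloid midpoint. The glenohumeral (shoulder) point is
approximated by the right acromion marker offset 30 mm caudally along
the sternum axis, and the glenoid by the same point — the marker set
contains no direct glenoid observation, and a fixed caudal offset is
the simplest construction that is exactly invertible by the synthetic
generator. The acromion line runs right → left.

## Angle system

- **θ_g (gravitational elevation)** — angle between the wrist vector
  (shoulder → wrist) and gravity; 0° hanging, 180° overhead.
- **Plane of elevation** — spanned by the wrist vector and gravity; its
  horizontal trace `u` orients all projected angles. Frames with the
  arm within ~1° of vertical have no defined plane; they are flagged
  and excluded from plane-dependent angles, never interpolated (the
  only exception: flagged frames are bridged linearly *inside* the
  low-pass filter to keep it stable, and restored to NaN afterwards).
- **κ (trunk compensation)** — the sternum axis of the current and the
  initial frame are projected onto the plane of elevation; κ is the
  signed angle between the projections. The sign convention is chosen
  so that a lean which carries the arm toward larger θ_g is positive,
  hence **θ = θ_g − κ** removes the compensation. κ of the initial
  frame is 0 by definition.
- **α (plane-of-elevation angle)** — angle between the horizontal
  projections of the initial acromion line and the glenoid → wrist
  line, taken toward the instrumented (right) side: pure sideward reach
  0°, straight forward 90°, cross-body up to 180°. Flexion trials
  target α = 80°, abduction α = 30°.
- **ρ (scapular rotation)** — angle of the scapular medial-border axis
  (superior → inferior) against gravity, signed in the plane of
  elevation; negative values are medial winging. **θ_GH = θ_g − ρ.**
  The identities θ = θ_g − κ and θ_GH = θ_g − ρ hold exactly in all
  outputs.
- **ScAla score** — reported as 1:x with x the least-squares slope of ρ
  against θ_GH over an ascent covering at least 20° of θ_GH. The slope
  generalises a single-frame ratio (which is also provided): it is
  robust to the elevation at which the ratio is read. 1:0.5 is the
  physiological scapulohumeral rhythm.

The study's optical marker set never saw the scapula (it was covered
by the assisting hand or the orthosis), so ρ enters the pipeline either
as an externally annotated series or via two *synthetic* scapula
medial-border annotation markers that the generator can emit; real
recordings without either simply lack ρ and θ_GH.

## Filtering, segmentation, repetition selection

Angle series are filtered with a zero-phase (forward–backward)
Butterworth low-pass, order 4, cutoff 5 Hz — the standard phase-neutral
choice in movement analysis; the filter type/order is a package
decision. Angular velocity is the central difference of the filtered
angle.

Elevation events are maximal runs of |velocity| ≥ 7 °/s, classified by
sign and merged ascent + descent across the intervening hold; runs
shorter than 0.25 s are discarded as threshold chatter (the guard
duration is a package decision). The 7 °/s threshold is applied to the
θ_g velocity. The peak frame is the θ_g maximum within the event; κ and
θ are evaluated at that frame, on the filtered series. Per block and
direction only the second elevation is analysed; if only one event
exists it is used with a logged warning.

Functional-task elevations are split into ascent (> +10 °/s), hold and
descent (< −10 °/s); a missing descent flags the event incomplete.

## Smoothness

SPARC is the negative arc length of the normalized Fourier magnitude
spectrum of the velocity profile, zero-padded (level 4), truncated at
10 Hz and trimmed to the band where the normalized magnitude exceeds
0.05 — the reference parametrisation of the metric, recorded with every
value. It is computed on the angular (θ_g) velocity of ascent and
descent separately. The minimum-jerk profile
x(t) = A(10τ³ − 15τ⁴ + 6τ⁵) (peak velocity 1.875·A/T) is the
smoothness upper bound; at 90°/2 s/100 Hz its SPARC is −1.406.

## Orthosis force model

The cable is modelled as six straight segments (an out-and-back pass
per thorax anchor, configurable) with capstan attenuation
T_k = T₀·exp(−μ·Φ_k), where Φ_k accumulates the wrap angles of the
redirections passed (default π/2 each, measured values override) and
μ = 0.1. The effective normal force on the scapula interface is
N = Σ_k T_k·sin φ_k with φ_k the segment's anchor elevation angle.
N is linear in T₀, non-increasing in μ, and reduces to the frictionless
closed form N = T₀·Σ sin φ_k at μ = 0. Because the source study prints
no model equation, an independent 3D static-equilibrium oracle (summing
per-segment tension vectors built from explicit plate/anchor
coordinates) is the package's authority: model and oracle agree with
R² > 0.99 over random geometries, and the oracle rejects coordinate
sets whose implied anchor angles deviate more than 1° from the declared
ones. Skin-pressure checks use N/area against 16 kPa (short-term) and
4 kPa (long-term) limits, plus the literature bounds of 100 N anterior
and 82 N lateral stabilising force demand.

## Mixed-model statistics

Peak θ per analysed elevation is modelled as
`peak_theta ~ support * direction + (1 | participant) + ε` with
treatment coding (reference: unassisted, abduction). The fit is REML:
for the single variance ratio λ = σ_b²/σ_e², each participant's
covariance is σ_e²(I + λJ), which is inverted and log-determined in
closed form; the profiled REML criterion is minimised over λ by bounded
1-D optimisation (λ ∈ [0, 10⁴]), with the boundary λ = 0 checked
explicitly. The fit is deterministic given the data; a single
participant triggers an OLS fallback with a warning.

Post-hoc contrasts are Wald statistics on linear combinations of the
fixed effects; the family is {therapist−none, orthosis−none} ×
{flexion, abduction}, Holm-corrected. Confidence intervals are
normal-quantile (±1.96·SE) by default — the convention adopted where
the source is silent — with a t-quantile option (df = n − p). The
"orthosis" support level is represented by the strongest force level
per participant (the setting users rate most helpful); an
empirical-best option exists but induces selection bias in recovery
simulations.

Normalized effect measures: improvement relative to baseline
(θ_cond − θ_none)/θ_none; orthosis improvement relative to the
therapist's (participants with non-positive therapist improvement are
excluded with a logged reason, not errored); trunk compensation
normalized by elevation (κ/θ_g at peak) and its percent change vs
baseline; Borg exertion reduction mean(none) − mean(orthosis).

## Synthetic cohort generator

The generator emulates the crossover design: 8 participants × 8 blocks
(baseline, orthosis levels 1–6, therapist, order shuffled per
participant) × 2 directions (order shuffled) × 2 repetitions, one
elevation per scheduled trial. Each elevation is a minimum-jerk ascent
(2 s) to the condition-adjusted peak, a 5 s hold, and a minimum-jerk
descent (2 s), padded with 0.5 s rest — the hold duration is the study
condition, the 2 s transports are a package choice. Ground truth per
frame: θ (profile), θ_g = θ/(1−c), κ = c·θ_g with c the participant's
compensation slope scaled by the condition factor, ρ = x/(1+x)·θ_g for
ScAla ratio x, α constant at the direction target.

Population defaults are the study conditions: therapist gains
17.3°/11.2° (flexion/abduction) and strongest-orthosis gains 6.2°/5.8°
on average, with between-participant spreads back-computed from the
reported confidence intervals (SD ≈ CI half-width/1.96·√8: 10.9/9.4
and 8.3/4.0); orthosis gains grow linearly with force level;
compensation-slope reductions of 13.0%/23.8% (therapist) and
8.6%/15.1% (orthosis); baselines uniform on 85–125°; ScAla ratios
uniform on −0.4…0.2; compensation slopes uniform on 0.04–0.37 but
jointly bounded with the peak so θ_g stays below the physical 180°
(in the data steep compensators were also the lower elevators); marker
noise 1 mm SD isotropic per coordinate; trial-to-trial peak jitter
1.5° SD (matching the reported intra-participant CI widths). Every
stochastic draw is seeded; identical seeds give bit-identical output.

What the generator does *not* emulate: soft-tissue artefact,
marker occlusion/gap patterns, elbow flexion (the simulated arm is a
straight segment chain), therapist hand mechanics, muscle force or
fatigue, and within-trial variation of α. Passing recovery tests
therefore demonstrates the pipeline's correctness under the study's
geometry and noise scale, not robustness to every artefact of real
recordings.

## Problem sizes and tolerances

Round-trip checks use 100 random noise-free poses (errors ~1e-14°,
requirement < 0.1°). Force-model validation uses 100 random geometries.
Parameter recovery runs 100 replicate cohorts of 8 participants,
simulating the three headline blocks (baseline, strongest orthosis,
therapist — the blocks entering the headline contrasts) and comparing
Monte-Carlo means of the LMM estimates against the configured gains
within ±2 Monte-Carlo SE. Angle outputs are reported to one decimal;
the ScAla score to one decimal in its 1:x form.

## Known limitations

- ρ requires annotation (or the synthetic border markers); the package
  does not estimate scapular orientation from the ten-marker set.
- κ at very low elevations is undefined (no plane of elevation); the
  initial-frame convention κ = 0 anchors the series.
- The LMM supports a single random intercept; random slopes
  (participant-specific condition responses) are part of the generator
  truth but absorbed into the residual, which is the usual conservative
  simplification at n = 8.
- The capstan model treats cable segments as straight and friction as
  concentrated at redirections; fabric/strap compliance is out of scope.
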