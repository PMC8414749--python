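# scapkin

Upper-limb motion-capture analysis for studies of **external scapula
assistance** — quantifying how supporting a winging scapula (scapula
alata, e.g. in facioscapulohumeral dystrophy) changes arm elevation,
trunk compensation, movement smoothness and the forces a textile
scapula orthosis applies.

The package is aimed at movement scientists and rehabilitation
engineers who record optical marker trajectories of seated arm
elevations under different assistance conditions (unassisted, assisted
by a therapist, assisted by a cable-tensioned scapula orthosis) and
want a reproducible pipeline from raw markers to condition-effect
statistics.

## The analysis in brief

**Angle system.** From ten anatomical markers (sternum/thorax: IJ, PX,
C7, T8; both acromia; humeral epicondyles; radial/ulnar styloids) the
pipeline reconstructs, per frame:

- θ<sub>g</sub> — gravitational arm elevation: the angle between the
  wrist vector (shoulder → styloid midpoint) and gravity;
- κ — trunk compensation: the change of the sternum-vs-gravity angle
  relative to the initial posture, projected onto the plane of
  elevation;
- **θ = θ<sub>g</sub> − κ** — elevation corrected for trunk lean;
- α — plane-of-elevation azimuth (flexion target 80°, abduction 30°);
- ρ — scapular rotation against gravity, and
  **θ<sub>GH</sub> = θ<sub>g</sub> − ρ** — glenohumeral elevation.

The **ScAla score** 1:x is the regression slope of ρ on θ<sub>GH</sub>
over an ascent; 1:0.5 is the physiological scapulohumeral rhythm
(scapular rotation contributes one third of humeral elevation),
negative x indicates medial winging.

**Segmentation.** Angle series are low-pass filtered (zero-phase
Butterworth, 4th order, 5 Hz); elevation events are segmented at a
7 °/s threshold on the θ<sub>g</sub> velocity and the *second*
elevation per block and direction is analysed. Functional-task trials
are split into ascent / hold / descent at 10 °/s.

**Smoothness.** SPARC (spectral arc length) of the angular velocity,
with the minimum-jerk trajectory x(t) = A(10τ³ − 15τ⁴ + 6τ⁵) as the
smoothness upper bound (SPARC ≈ −1.4 for typical elevation durations).

**Orthosis force model.** The orthosis presses a plate onto the scapula
via a cable routed to three thorax anchors (capstan friction μ = 0.1):
T<sub>k</sub> = T₀·e^(−μΦ<sub>k</sub>) per segment and effective normal
force N = Σ T<sub>k</sub> sin φ<sub>k</sub>, validated against a 3D
static-equilibrium oracle and checked against the 16 kPa short-term /
4 kPa long-term skin-pressure limits.

**Statistics.** Peak θ per analysed elevation enters a random-intercept
linear mixed model, `peak_theta ~ support * direction +
(1 | participant)`, fitted by REML with the variance ratio profiled by
1-D optimisation; post-hoc Wald contrasts (therapist−none,
orthosis−none per direction) are Holm-corrected.

A **synthetic cohort generator** reproduces the study design (8
participants, 8 blocks — baseline, six orthosis force levels,
therapist — with 2 repetitions × 2 directions per block, 5 s holds,
millimetre marker noise) so every stage is testable without recorded
data; noise-free forward marker sets round-trip through the kinematics
to < 0.1°.

## Worked example

The numbered scripts under `analysis/` run the full synthetic study and
write small tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/03_segment_and_peaks.py
python analysis/04_condition_effects.py
```

`04_condition_effects.py` prints (seed-42 cohort):

```
REML fit on 48 analysed peaks: sd(participant) = 9.0 deg, sd(residual) = 5.2 deg
  therapist-none  abduction  +17.1 deg CI95 [ 12.0,  22.2]  p_holm=0.0000 (significant)
  therapist-none  flexion    +21.1 deg CI95 [ 16.0,  26.2]  p_holm=0.0000 (significant)
  orthosis-none   abduction   +6.3 deg CI95 [  1.2,  11.4]  p_holm=0.0294 (significant)
  orthosis-none   flexion     +2.8 deg CI95 [ -2.3,   7.9]  p_holm=0.2839 (n.s.)
mean trunk-compensation reduction vs baseline (%):
support    direction
orthosis   abduction    14.6
           flexion       9.1
therapist  abduction    23.7
           flexion      13.0
```

Reading: with therapist assistance this simulated cohort elevates the
arm on average 21.1° higher in flexion than unassisted (the CI is the
normal-quantile 95% interval of the contrast); the orthosis effect is
smaller and, in flexion for this particular cohort draw, not
significant after Holm correction. Trunk compensation per degree of
elevation drops under both forms of assistance.

The same stages are scriptable through the `scapkin` CLI
(`simulate`, `angles`, `segment`, `smoothness`, `force`, `effects`,
`report`), e.g.:

```sh
scapkin simulate --out trials/ --seed 5 --max-trials 2
scapkin angles --in trials/trial_000.tsv --out angles.csv
scapkin segment --in angles.csv --task rom --out events.csv
```

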