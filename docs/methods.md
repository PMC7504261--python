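# Methods

This note documents the models behind `ergopose`, the parameters that
matter, the synthetic data used to test them, and the design choices made
where the design was genuinely open.

## Input model

Kinematic input is the per-frame export of a full-body inertial
motion-capture pipeline: 3-component angles (flexion/extension,
abduction/adduction, internal/external rotation; degrees) for a 22-joint
skeleton, and global 3D positions (metres) for 23 segment origins. The
joint/segment inventory (`ergopose.body`) follows the common commercial
suit layout: a 7-link axial chain, two 4-link arms, two 4-link legs.

Files are delimited text with a one-line metadata header (frame rate,
units, up/forward axes) plus a column-name line; a minimal XML dialect is
also read. Units are asserted on read. Two policies are deliberate:

* **Missing frames are an error, never interpolated.** Risk scores are
  per-frame; silently gap-filling would fabricate postures. A gap is
  detected as a frame interval exceeding 1.5× the median interval.
* **Rigid-body sanity check.** Distances between connected segment origins
  must vary < 5 % over a series; violations indicate a corrupted or
  mis-labelled export.

Channel names are canonicalised through an alias table
(`jRightShoulder_flexion` ⇐ "Right Shoulder Flexion/Extension", …) because
mocap vendors do not share a schema. Frames are 0-indexed and time runs in
seconds from the first frame.

## Region mapping for postural scoring

The scoring instruments are defined on *regional* angles an observer would
judge, not on individual intervertebral joints. The mapping (in
`ergopose.scoring`) is: trunk angle = sum of the four lumbar/thoracic joint
angles; neck = sum of the two cervical joints; upper arm / lower arm /
wrist angles come from the shoulder, elbow and wrist joints of each side;
shoulder-girdle elevation from the C7–shoulder joint. Boolean cues use
declared thresholds shipped alongside the tables (abduction > 45°,
twist/side-bend > 20°, wrist deviation > 15°, girdle elevation > 15°,
rotation cues > 60°). A ±5° neutral tolerance around 0° keeps
"upright"/"straight" judgements robust to sensor noise; without it, a 0.1°
flexion reading would flip e.g. the neck score from 1 to the extension
score. These thresholds are configuration, not facts of the instruments,
and live in `data/rula_tables.yaml` / `data/reba_tables.yaml` (versioned,
human-readable).

Both upper limbs are scored and the frame reports the **worse side** (ties
to the right). The instruments are side-specific but a per-frame series
needs a single number; the worse side is the conservative choice.

## Look-up tables

The RULA and REBA threshold bins, tables A/B/C, force/load bands, coupling
and activity scores are transcribed from the original worksheets into the
YAML data files. The test suite carries a *second, independent*
transcription in a different encoding and checks the full chain by
exhaustive enumeration over every valid region-score tuple (zero mismatches
required), plus monotonicity of the grand score in load, coupling, muscle
use.

Risk bands: RULA 1–2 negligible, 3–4 low, 5–6 medium, 7 high; REBA 1
negligible, 2–3 low, 4–7 medium, 8–10 high, 11–15 very high. The RULA
wording commonly quoted ("medium 5–6, high 6+") overlaps at 6; this package
resolves 6 → medium, 7 → high so the bands partition the 1–7 range. The
band map is data, so a user who prefers 6 → high can override it.

RULA region scores outside a table's domain raise an error rather than
clamp — a clamped score would silently mis-rate extreme input. The
published 8+/7+ saturation rows of RULA table C (and 12 rows of REBA table
C) are part of the instruments and are applied.

## 2D static biomechanical model

Positions are projected into the sagittal plane before analysis. The
default plane is **pelvis-heading**: spanned by gravity and the horizontal
forward vector derived per frame from the hip segment positions, so a
subject who has turned away from the global axes is still analysed in their
own sagittal plane; `global-xz` is available as a fallback and for
axis-aligned recordings. Projection keeps (in-plane horizontal, vertical)
and discards the lateral component, hence it is a contraction and is
idempotent on planar data.

The eight linkage joints are derived from the segment cloud by averaging
left/right origins (ankle ⇐ feet, knee ⇐ shanks, hip ⇐ thighs, shoulder ⇐
upper arms, elbow ⇐ forearms, wrist ⇐ hands; L5/S1 ⇐ the L5 origin). The
grip point extends the wrist along the forearm by 0.37 of the forearm
vector, landing near the hand's centre of mass where a hand-held load acts.

**Statics.** The posture is assumed symmetric (bilateral segments lumped at
the midline with doubled mass) and static (zero acceleration). A
distal-to-proximal recursion over hand → forearm → upper arm → upper trunk
(head/neck attached as a point mass above the shoulder) → pelvis link →
thigh → shank accumulates supported weight and sagittal moment; the moment
at a joint is Σ mᵢ g (xᵢ − x_joint) over everything distal plus the load.
Each frame re-checks itself against a direct free-body summation and
reports the worst residual (≈ 10⁻¹³ in practice). Positive moment means the
supported mass lies anterior to the joint.

**Anthropometry.** `data/anthropometry.csv` carries per-segment mass
fraction of body mass, length fraction of stature, and centre-of-mass
fraction from the proximal end, in the ranges of the standard
segment-parameter compilations (Winter-style mass/COM fractions,
Drillis–Contini length ratios). Counting bilateral segments twice the mass
fractions sum to exactly 1. The table is overridable; defaults are scaled
by the subject's mass and stature (`default_anthropometry`).

**L5/S1 disc loads.** With M the L5/S1 moment, θ_T and θ_H the trunk and
thigh inclinations from the horizontal (degrees), W the superincumbent
weight including the load:

* abdominal pressure `P_A = 1e-4 · max(0, 43 − 0.36(θ_H+θ_T)) · |M|^1.8`
  (mmHg) — the classic empirical relief term: pressure grows with the
  extensor demand and is suppressed in upright postures (the angle factor
  clamps to 0 near standing, where M is small anyway);
* abdominal force `F_A = P_A · A`, diaphragm area A = 0.0465 m², acting
  upward at moment arm D = 0.11 m anterior to the disc;
* erector-spinae force `F_M = max(0, (|M| − F_A·D)/E)`, single equivalent
  extensor at moment arm E = 0.05 m; the zero floor encodes that no active
  flexor is modelled when abdominal relief exceeds demand;
* the disc normal is taken along the trunk axis, so
  `F_C = W·sin θ_T + F_M − F_A` and `F_S = W·cos θ_T`.

All constants live in `L5S1Config` and the pressure model is pluggable. For
the default subject (68.4 kg, 1.731 m — the mean build of a young male
cohort) a 70° stoop holding 5 kg yields F_C ≈ 3.2 kN, just under the
widely used 3.4 kN action limit; upright standing yields F_C equal to the
superincumbent weight (≈ 0.36 kN). Compression is monotone in load and
invariant under mirroring the posture.

**Strength percent capable.** Population static strength per joint and
moment direction is modelled as Gaussian; `% = Φ((μ − |M|)/σ)·100`. The
shipped `data/strength_table.csv` holds literature-informed means/SDs (N·m)
for elbow, shoulder, torso, hip, knee, ankle in both directions for a
combined adult population; it is a self-contained default intended to be
replaced with a user's preferred strength database via
`load_strength_table(path)`. The moment sign selects the muscle group
(mass-anterior torso moment → extensors, etc.). Analysed joints default to
elbow, shoulder, torso (L5/S1), hip, knee, ankle.

## Validation statistics

* **ICC**: two-way random effects, absolute agreement, single measures —
  ICC(2,1) — computed from the two-way ANOVA variance components (via
  pingouin), with the standard F-based 95 % CI. This variant is the
  defensible default for "same scores, interchangeable raters" absolute
  comparisons; the variant argument exists so others can be added. Bands:
  < 0.4 poor, 0.4–0.6 fair, 0.6–0.75 good, ≥ 0.75 excellent reliability.
  Zero total variance raises an explicit undefined-statistic error.
* **Intersystem CMC**: the between-protocol formulation from the gait
  literature, `sqrt(1 − [Σ(y_fs − ȳ_f)²/(F(S−1))] / [Σ(y_fs − ȳ)²/(FS−1)])`
  on time-aligned frames×systems waveforms; a negative radicand (systems
  less similar than chance) clips to 0 with a warning. Bands: > 0.9 strong,
  0.5–0.9 moderate, 0.25–0.5 weak, ≤ 0.25 poor association.
* **Relative error**: `100·RMSE/max(reference)`.
* **Risk confusion**: K×K counts (system rows × reference columns) over
  ordinal risk labels; accuracy = trace/total.
* **Absolute differences**: mean ± SD and the empirical central 95 %
  interval (2.5th–97.5th percentiles) of |system − reference|.

## Synthetic motion

The generator (`synthmotion`) emulates the study conditions under which
such systems are validated: canonical industrial postures — neutral
standing, stooped lifts with graded trunk flexion and twist (5 kg loads),
squat lifts, overhead work, wall painting on vertical and sloped surfaces,
welding in several positions, carrying — held for a duration at a frame
rate, with independent Gaussian angle noise per channel per frame, and task
cycles interpolated between posture keyframes along a monotone smoothstep.
Defaults: 68.4 kg / 1.731 m subject, 20 Hz, 1 s holds, zero noise; a fixed
seed fixes the full output.

Positions are built by forward kinematics over a skeleton using the *same*
anthropometric length fractions as the biomechanics module, so angle and
position files are mutually coherent — re-deriving the linkage inclination
angles from generated positions recovers the generating angles to < 0.1°
(verified in tests). Trunk twist/side-bend rotate the upper body rigidly
about L5/S1, which reproduces the cosine foreshortening a projection must
show.

Each of the 25 named battery postures carries a frozen `OracleLabel`
(expected zero-noise RULA/REBA grand scores and risk levels) derived from
an independent transcription of the scoring worksheets — never from the
package's own scoring code — so the end-to-end pipeline has exact expected
outputs. The battery spans RULA grands 2–7 and REBA grands 1–8 plus 15.

What the generator does *not* emulate: autocorrelated sensor noise and
drift, soft-tissue artefact, asymmetric postures, inter-subject
anthropometric variation, and real task dynamics. Passing tests therefore
demonstrate correctness of the scoring/statics pipeline given clean
kinematics, not field accuracy of any sensor system.

## Numerical choices and degenerate inputs

* Gravity 9.80665 m/s²; mmHg → Pa 133.322.
* Half-open angle bins (lower ≤ θ < upper); battery angles avoid bin edges.
* Earliest-frame tie-break for "find max".
* Degenerate pelvis heading (coincident hips) raises a projection error
  with a pointer to the global-XZ fallback.
* CSV floats are written with 17 significant digits and parsed with
  round-trip precision, so write→read is bit-exact.
* The equilibrium re-check compares the recursion against direct summation
  per frame; residuals above ~1e-9 would indicate a broken chain.

## Acceptance script problem sizes

`scripts/acceptance.py` uses the full 300-observation published agreement
counts, the complete 25-posture battery, 100 random planar postures for
the statics residual, and a 70-frame noisy lift cycle measured twice —
sizes chosen to exercise every pipeline stage while completing in seconds.

## Known limitations

The biomechanical model is 2D and static: asymmetric or dynamic tasks are
outside its validity, and 3D inverse dynamics would be the next step. The
single-equivalent-muscle L5/S1 balance ignores co-contraction, so
compression is likely underestimated in guarded postures. The strength
table is a generic combined-population default, not a per-percentile
database. REBA's "legs unsupported" and RULA's "shoulder raised" cues are
only partly derivable from kinematics and fall back to analyst flags.
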