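# Methods

This note documents the models, numerical choices, and limitations behind
`mdtt`. It is the design record: every empirical statement here is computed
by the test suite or by `scripts/acceptance.py`.

## Problem setting

Liver targets move with respiration, dominantly superior–inferior (SI), and
are usually invisible on kV x-ray. Dynamic tumor tracking therefore relies
on implanted fiducial seeds — unless a visible soft-tissue structure can
stand in for them. The diaphragm dome is the natural candidate: it is
high-contrast on fluoroscopy and sits directly above superior liver
lesions. The package models the complete markerless-tracking analysis chain
on an O-ring gantry linac with two kV imagers at ±45° from the treatment
beam axis: stereo imaging geometry, structure detection, 3D reconstruction,
respiratory correlation modelling against an external infrared (IR) chest
surrogate, tracking verification with beam gating, and population error /
planning-margin statistics.

## Coordinate conventions and imaging geometry (`mdtt.geometry`)

* Room frame: right-handed, origin at isocenter, x = ML, y = SI, z = AP.
  All positions in mm. The machine's ring rotates about the room vertical
  (AP) axis first; the gantry then rotates about the ring-rotated
  longitudinal (SI) axis. Machine vendors do not publish a canonical frame
  for this geometry; these conventions are fixed package-wide and tested,
  not inferred.
* Each imager is modelled by its source at SAD = 1000 mm and a detector at
  the *isocenter-plane-equivalent* scale: the 216 mm × 162 mm field of view
  maps to the 1024 × 768 matrix at the plane through the isocenter
  perpendicular to the central axis, i.e. a pixel pitch of
  216/1024 = 162/768 = 0.2109375 mm. This sidesteps the unpublished
  physical source–detector distance; only ratios matter for back-projection.
* Pixels are 0-based and address pixel centers; the principal point is the
  matrix center (511.5, 383.5). Detector rows advance in the inferior
  direction (radiograph orientation).
* Stereo localization: a detector coordinate back-projects to the ray
  through the source; two rays from paired frames generally are skew, and
  the reported 3D position is the midpoint of their common perpendicular,
  with the segment length stored as a residual (mm). Rays with a direction
  cross-product norm below 1e-12 are rejected as parallel. The
  project → back-project → intersect round trip is exact to < 1e-9 mm for
  points within ±100 mm of the isocenter at arbitrary gantry/ring angles.

## Digital phantom and session simulator (`mdtt.phantom`)

The simulator emulates an acrylic dome ("diaphragm") insert on a breathing
motion platform, with three 1 mm × 3 mm gold seeds embedded 17–82 mm
inferior to the dome (default ≈ 39 mm), plus an external chest surrogate.

**Image formation is a 2D silhouette model, not ray-traced attenuation.**
Each frame renders the projected dome interface as a smooth intensity ramp
(bright lung above, darker liver below; ramp width 3 px) and each seed as a
dark anisotropic Gaussian blob whose FWHM equals the physical seed size at
the isocenter-plane scale. This is precisely the information a normalized
cross-correlation detector uses; scatter, beam hardening, heel effect and
panel distortion are out of scope. Consequences: detection on synthetic
frames is cleaner than clinical reality, and tests passing here bound the
algorithmic errors, not clinical detectability.

The dome surface carries a small material indentation (depth 2 mm, ~8° off
apex — a cardiac-impression analogue). Without it the projected interface
is a smooth symmetric arc for which a vertical shear (caused by
differential magnification under SI motion) is geometrically
indistinguishable from a lateral slide, making along-interface localization
ill-posed. Real diaphragm silhouettes are not featureless; the dimple plays
that role.

**Breathing traces.** The `sinusoid` pattern reproduces the platform
protocol: SI peak-to-peak exactly equal to the programmed amplitude
(default 22.5 mm at 6 breaths/min), pure SI, external signal a scaled copy.
The `perturbed` pattern adds per-cycle amplitude jitter (envelope anchored
at cycle peaks so drawn amplitudes are realized exactly), period jitter, a
linear baseline drift, ML/AP internal components as fixed fractions of SI,
a hysteresis lag between the external phase and the internal motion
(producing loop-shaped internal-vs-external curves), and measurement noise
on the external channel only. `patient_like_trace()` freezes one set of
plausible scales (15 mm p2p at 7.5 BPM; 8 %/6 % amplitude/period jitter;
0.8 mm/min drift; 0.3 s lag; 0.05 mm external noise; ML/AP fractions
0.10/0.25). No public patient-trace model exists for this workflow; these
are generator choices at clinically reported orders of magnitude, not
fitted values — results on them characterize the pipeline, not any cohort.

**Noise model.** Additive Gaussian counts (default SD 300 on a ~14000-count
edge) and isolated dead pixels pinned to 0 or 65535 (default 20/frame),
placed with no 8-adjacency so a 3×3 median filter removes them exactly.

**Frame-rate policies** mirror the clinical regimes: `model_building`
(~5 fps, 20–40 s), `verification` (~1 Hz), `template` (13-frame burst).
A single seed drives all stochastic sub-steps through spawned
sub-generators; identical configuration + seed reproduces bit-identical
pixels.

## Detection (`mdtt.detection`)

Preprocessing converts each 16-bit frame to 256 gray levels (linear
min→0 / max→255; a constant frame maps to zeros) and applies a 3×3 median
filter with reflected edges. Template matching is normalized
cross-correlation over a windowed search, refined to sub-pixel by a
per-axis parabolic fit to the 3×3 score neighborhood (clamped to ±0.5 px;
flat or non-concave neighborhoods contribute zero offset). Matches below
NCC 0.5 are flagged low-confidence, never silently dropped.

The diaphragm is represented as points on a line. Two tracking modes:

* **Fixed-column (default).** Each line point keeps its seeded column and
  only its vertical position is searched. Exact for SI-dominant motion and
  immune to tangential sliding; ML/AP motion of the structure is not
  observed. This is the mode for the platform protocol, whose motion is
  purely SI.
* **Lateral (`track_lateral=True`).** A wide template spanning the whole
  interface arc is matched first; its overall curvature plus the surface
  dimple localize the structure's global 2D shift, and the per-point column
  bands ride on that shift. This follows ML/AP motion at the cost of a few
  tenths of a millimeter of lateral noise — which is also the realistic
  scale of clinical diaphragm-tracking uncertainty.

Sequences propagate frame to frame: windows center on the previous frame's
confident detections (or the prior, on a brief loss); a structure
low-confident for 5 consecutive frames flags the sequence as lost. Search
half-width defaults to 20 px (~4 mm at isocenter; per-frame motion at 5 fps
is ~3 px). For ~1 Hz verification imaging, where inter-frame motion reaches
~6 mm, a 50 px half-width is used. Template size (21×21), thresholds and
window sizes are all `DetectionConfig` fields.

Seeding replicates the clinical manual-alignment step (the user drags the
projected contour onto the first image pair): the CLI accepts explicit
initial positions; simulations seed from ground truth.

## Reconstruction (`mdtt.reconstruction`)

Markers: each seed is triangulated separately from its A/B detections and
the three 3D points are averaged into the marker COM — exact in the
noiseless limit, unlike averaging in 2D first, which mixes perspective
scales. Diaphragm: the per-imager 2D line COMs are triangulated directly,
matching the workflow's single-COM-per-image representation. Because the
mean of projections is not the projection of the 3D mean under perspective,
this construction carries a small constant posterior offset growing with
the arc's lateral spread (≈0.43 mm for a ±35° arc, ≈0.04 mm for the
default ±10° arc — the reason the tracked sub-arc is narrow). Frames pair
by timestamp within 1 ms; per-pair ray residuals above 2 mm are flagged.

`compare_traces` reports per-axis absolute differences (mean, and SD with
the n−1 denominator — used consistently for every SD in the package). By
default raw positions are compared; with `center=True` each trace is first
reduced to displacement about its own time-mean, the relevant comparison
when the two structures sit centimeters apart and only their *motion*
agreement is in question (this is what the diaphragm-as-surrogate analysis
uses). Whether the published SD columns describe absolute or signed
differences is ambiguous; absolute is used throughout.

## Correlation model (`mdtt.correlation`)

The clinical system's model family is proprietary. Each axis is fit by
ordinary least squares to

    pos = a0 + a1·s + a2·s² + b1·v

with s the external surrogate displacement (single scalar channel — the
principal axis of the IR pad; the 4-marker pad geometry is out of scope)
and v its finite-difference velocity (central differences, one-sided ends).
The quadratic captures amplitude nonlinearity; the velocity term separates
inhale from exhale and absorbs hysteresis (on a phase-lagged synthetic
session it cuts the SI residual by ~7× versus the velocity-free fit). The
design-matrix builder is a single function, so richer forms can be swapped
in. Fitting requires ≥ 20 time-matched samples and a full-rank design;
coefficient standard errors come from the unbiased residual variance and
(XᵀX)⁻¹. Predictions outside the fitted signal/velocity range by > 10 % of
its span are flagged as extrapolation.

Verification compares detected vs predicted positions at ~1 Hz: the record
stores the 3D vector difference and the beam status, HOLD iff the
difference *strictly* exceeds the tolerance (default 3 mm; equality keeps
the beam on — the boundary case is documented and tested). The package
reports the hold fraction; automatic model rebuilding is intentionally not
triggered, since the clinical update criteria are unpublished.

## Margins (`mdtt.margins`)

Per patient, a deviation series reduces to its mean absolute deviation and
SD. Across patients: systematic error Σ = SD (n−1) of per-patient means;
random error σ = RMS of per-patient SDs; mean-of-means as the headline
deviation. Independent sources combine in quadrature. The CTV-to-PTV margin
is k_sys·Σ + k_rand·σ with the classic 2.5/0.7 defaults, both configurable
and echoed in the result. Rounding for report-time comparison is half-up at
2 decimals (`round_half_up`, decimal-exact so representation error cannot
flip half-way cases); internal computation keeps full precision.

The study's per-patient deviation tables ship as CSV fixtures
(`mdtt/data/table1..4.csv`); aggregating them reproduces every printed
population row exactly at 2 decimals — which also validates the n−1
convention. The published per-axis margin values are *not* reproducible
from the printed tables under this (or any per-axis/quadrature) combination
rule; the combination actually used there is unstated. The package
therefore reports margins under its own declared rule (per-axis surrogate
error ⊕ 3D tracking error in quadrature, 2.5/0.7) rather than claiming to
match.

## Problem sizes and numerical choices

Simulated protocols use the workflow's own scales: 40 s × 5 fps model
building (201 frame pairs), 84–85 s × 1 Hz verification, 10–20 s sessions
for unit-level checks. Parameter-recovery statistics use n = 200 samples,
0.3 mm noise, 100 replicates. Key tolerances: geometric round trip 1e-9 mm;
noiseless pipeline truth recovery 0.1 mm RMS per axis; rigid-phantom motion
agreement 0.05 mm; programmed-amplitude recovery 0.3 mm at study noise;
coefficient recovery within 3 SE in ≥ 95 % of replicates. Degenerate inputs
(constant images, constant surrogate, parallel rays, single-sample series,
sub-minimum line points) raise or flag explicitly rather than returning
silent values.

## Known limitations

* Silhouette rendering omits attenuation physics; absolute NCC scores on
  clinical images will be lower and the confidence threshold may need
  retuning there.
* The lateral tracking mode's ML/AP noise floor (~0.1–0.3 mm) is set by the
  edge's shear/slide near-degeneracy; structures with stronger asymmetric
  features track better.
* The correlation-model family is a stand-in chosen for parsimony, not a
  reimplementation of any vendor's proprietary model; equivalence at the
  workflow level only.
* Gimbal mechanics and tracking latency (< 50 ms clinically), moving-
  isocenter bookkeeping, MV delivery, film dosimetry and imaging dose are
  out of scope.
* Fixture-based statistics inherit the 2-decimal precision of the printed
  per-patient values.
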