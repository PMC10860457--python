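# mdtt — markerless dynamic tumor tracking analysis

Respiratory motion moves liver targets by one to several centimeters,
dominantly superior–inferior (SI), and liver lesions are essentially
invisible on kV x-ray — which is why tracked radiotherapy traditionally
requires implanted gold fiducials, with the attendant procedure risks.
`mdtt` is a research toolkit for the markerless alternative: tracking the
**diaphragm dome** as a soft-tissue surrogate on a dual-orthogonal kV
imaging system (two tubes at ±45° from the treatment beam axis of an
O-ring gantry linac), and quantifying how well that surrogate stands in
for the markers.

The package provides, as an importable library:

* **geometry** — stereo projection/back-projection for both kV imagers
  under arbitrary gantry/ring rotations; skew-ray intersection with
  closest-approach residuals;
* **phantom** — a digital dome-and-seeds breathing phantom: sinusoidal
  (motion-platform) and irregular patient-like traces, a phase-linked
  external IR chest surrogate, and rendered 16-bit fluoroscopy frame pairs
  with ground truth;
* **detection** — 256-level conversion, median dead-pixel filtering, and
  normalized cross-correlation (NCC) template matching with sub-pixel
  refinement; diaphragm line points and fiducial markers propagated across
  sequences;
* **reconstruction** — 3D motion traces at the isocenter from paired 2D
  detections; diaphragm-vs-marker motion comparison statistics;
* **correlation** — the respiratory correlation model
  `pos = a0 + a1·s + a2·s² + b1·v` per axis (surrogate displacement `s`,
  velocity `v` for hysteresis), prediction, residual statistics, and ~1 Hz
  tracking verification with beam gating (HOLD iff ‖detected − predicted‖ >
  tolerance, default 3 mm);
* **margins** — population error decomposition (systematic
  Σ = SD of per-patient means; random σ = RMS of per-patient SDs) and the
  van Herk CTV-to-PTV margin `2.5 Σ + 0.7 σ`, with the study's per-patient
  deviation tables packaged as CSV fixtures.

`examples/` contains one short narrative script per capability. A thin CLI
(`mdtt simulate|track|compare|margins|report`) wraps the library for
shell-driven runs; see `mdtt --help`.

## Worked example

Simulate the motion-platform protocol — a 22.5 mm SI peak-to-peak sinusoid
at 6 breaths/min imaged at ~5 fps — and push it through detection and
stereo reconstruction (`examples/02_phantom_session.py`):

```
rendered 101 frame pairs at ~5 fps
diaphragm SI peak-to-peak: 22.50 mm (programmed 22.50 mm)
markers   SI peak-to-peak: 22.51 mm
ML: mean |diaphragm - marker| motion difference 0.001 mm
SI: mean |diaphragm - marker| motion difference 0.003 mm
AP: mean |diaphragm - marker| motion difference 0.001 mm
```

The pipeline recovers the programmed amplitude to hundredths of a
millimeter, and on this rigid phantom the dome and the embedded seeds move
identically — the per-axis differences are the detection noise floor.

Aggregate the packaged per-patient tables into population errors and
margins (`examples/04_margins.py`):

```
tracking: mean 2.02 mm, Sigma 0.64, sigma 0.92
ML: surrogate Sigma/sigma 0.34/0.89 mm -> margin 2.7 mm
SI: surrogate Sigma/sigma 0.86/1.26 mm -> margin 3.8 mm
AP: surrogate Sigma/sigma 0.77/1.06 mm -> margin 3.5 mm
```

Here Σ (systematic) shifts the dose distribution and σ (random) blurs it;
the margin line combines the diaphragm-vs-marker surrogate error with the
3D tracking-verification error in quadrature under the declared
`2.5 Σ + 0.7 σ` rule (coefficients configurable and echoed in every
result).

See `docs/methods.md` for the models, conventions, numerical choices and
their limitations.

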