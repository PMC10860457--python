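"""Simulate the motion-platform protocol and recover the programmed motion.

Renders a short dual-orthogonal fluoroscopy session of the dome phantom
driven by a 22.5 mm / 6 BPM sinusoid, runs NCC detection and stereo
reconstruction, and compares the recovered SI peak-to-peak amplitude with
the programmed value.
"""

import numpy as np

from mdtt import (ImagingGeometry, compare_traces, default_phantom,
                  make_breathing_trace, reconstruct_session)
from mdtt.phantom import NoiseParams, simulate_session

phantom = default_phantom()
geom = ImagingGeometry()
trace = make_breathing_trace("sinusoid", amplitude_mm=22.5, rate_bpm=6,
                             duration_s=20.0, sample_hz=25.0)
session = simulate_session(phantom, geom, trace, "model_building",
                           NoiseParams(), seed=7)
print(f"rendered {session.n_pairs} frame pairs at ~5 fps")

diaphragm, markers = reconstruct_session(session)
print(f"diaphragm SI peak-to-peak: {diaphragm.si_peak_to_peak:.2f} mm "
      f"(programmed 22.50 mm)")
print(f"markers   SI peak-to-peak: {markers.si_peak_to_peak:.2f} mm")

cmp_ = compare_traces(diaphragm, markers, center=True)
for k, ax in enumerate(("ML", "SI", "AP")):
    print(f"{ax}: mean |diaphragm - marker| motion difference "
          f"{cmp_.mean[k]:.3f} mm")
# On this rigid phantom the dome and the seeds move together, so the
# per-axis motion differences are essentially the detection noise floor.
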