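"""Shared fixtures: small simulated fluoroscopy sessions reused across tests.

Sessions are session-scoped because rendering hundreds of 1024x768 frames
dominates suite runtime; tests must not mutate them.
"""

import numpy as np
import pytest

from mdtt import ImagingGeometry, default_phantom, make_breathing_trace
from mdtt.phantom import NoiseParams, simulate_session
from mdtt.reconstruction import reconstruct_session


@pytest.fixture(scope="session")
def geom():
    return ImagingGeometry()


@pytest.fixture(scope="session")
def phantom():
    return default_phantom()


@pytest.fixture(scope="session")
def sinusoid_trace():
    """Platform-programmed breathing: 22.5 mm SI peak-to-peak at 6 BPM."""
    return make_breathing_trace("sinusoid", 22.5, 6, 10.0, 25.0, external_gain=0.4)


@pytest.fixture(scope="session")
def noiseless_session(phantom, geom, sinusoid_trace):
    """10 s noiseless sinusoid session (51 frame pairs at ~5 fps)."""
    return simulate_session(
        phantom, geom, sinusoid_trace, "model_building", NoiseParams.none(), seed=101
    )


@pytest.fixture(scope="session")
def noisy_session(phantom, geom, sinusoid_trace):
    """Same session at the study's default detector noise level."""
    return simulate_session(
        phantom, geom, sinusoid_trace, "model_building", NoiseParams(), seed=102
    )


@pytest.fixture(scope="session")
def noiseless_traces(noiseless_session):
    """Truth-seeded pipeline output (diaphragm trace, marker trace)."""
    return reconstruct_session(noiseless_session)


@pytest.fixture(scope="session")
def noisy_traces(noisy_session):
    return reconstruct_session(noisy_session)


def truth_at(session, times, which="diaphragm"):
    """Ground-truth positions of a session at given frame times."""
    idx = np.searchsorted(session.truth_times, times)
    arr = session.truth_diaphragm if which == "diaphragm" else session.truth_markers
    return arr[idx]
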