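"""Digital liver/diaphragm phantom and dual-orthogonal fluoroscopy simulator.

The physical analogue is an acrylic dome ("diaphragm") insert riding on a
respiratory motion platform, with three small gold seeds embedded inferior
to the dome as fiducial markers, and an external infrared (IR) chest
surrogate moving in phase with the internal motion. This module renders
that scene onto the two orthogonal kV imagers so the full detection /
back-projection / correlation-model pipeline can be exercised against known
ground truth.

Image formation is deliberately a 2D silhouette model, not ray-traced
attenuation: the dome appears as a smooth intensity edge (bright lung above
the interface, darker liver below) and each seed as a high-contrast
elongated blob. That is the information content the normalized
cross-correlation detector actually uses; x-ray scatter, beam hardening and
panel distortion are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .frames import FluoroFrame, FluoroSequence
from .geometry import ImagingGeometry, PixelCoord, RoomPoint, project_point

__all__ = [
    "DigitalPhantom",
    "BreathingTrace",
    "NoiseParams",
    "SimulatedSession",
    "make_breathing_trace",
    "render_frame",
    "simulate_session",
    "default_phantom",
]

#: 16-bit rendering levels: lung (above interface), liver (below), and the
#: depth of the dark marker blobs relative to the liver background.
LUNG_LEVEL = 40000.0
LIVER_LEVEL = 26000.0
MARKER_DEPTH = 14000.0


@dataclass(frozen=True)
class NoiseParams:
    """Detector noise model: additive Gaussian counts plus dead pixels.

    Dead pixels are isolated single pixels pinned to 0 or 65535, emulating
    the panel defects the preprocessing median filter must remove.
    """

    gaussian_sd: float = 300.0
    dead_pixels: int = 20

    @staticmethod
    def none() -> "NoiseParams":
        return NoiseParams(gaussian_sd=0.0, dead_pixels=0)


@dataclass(frozen=True)
class DigitalPhantom:
    """Dome-shaped diaphragm phantom with embedded fiducial markers.

    The dome is a spherical cap whose apex is its most superior point; the
    tracked "diaphragm line" is a material arc on the cap surface in the
    ML-SI plane. Markers sit inferior to the apex (configurable over the
    study's 17-82 mm range of marker-to-dome SI distances).

    ``marker_motion_scale`` < 1 makes the markers move with a smaller
    amplitude than the dome (deformable anatomy); 1.0 is the rigid phantom.
    """

    apex: RoomPoint = RoomPoint(0.0, 12.0, 0.0)
    radius: float = 60.0
    cap_height: float = 25.0
    #: Rest positions chosen so the three seeds stay well separated in the
    #: projections of BOTH oblique imagers (their u axes mix ML and AP).
    markers: tuple = (
        RoomPoint(-14.0, -20.0, 5.0),
        RoomPoint(13.0, -27.0, -6.0),
        RoomPoint(2.0, -33.0, 12.0),
    )
    marker_size: tuple = (1.0, 3.0)  # mm: (transverse, SI length)
    tissue_contrast: float = LUNG_LEVEL - LIVER_LEVEL
    marker_motion_scale: float = 1.0
    edge_ramp_px: float = 3.0
    #: Local indentation of the dome surface (depth mm, angular position
    #: and width in deg). A perfectly smooth symmetric cap is degenerate
    #: for image tracking: a vertical shear of its projection (differential
    #: magnification under SI motion) is indistinguishable from a lateral
    #: slide. Real diaphragm silhouettes carry asymmetric features (e.g.,
    #: the cardiac impression); this dimple plays that role and anchors
    #: the along-interface localization.
    dimple_depth: float = 2.0
    dimple_theta_deg: float = 8.0
    dimple_sigma_deg: float = 4.0
    n_interface_points: int = 5
    #: Angular span of the tracked sub-arc about the apex. Kept narrow so
    #: the 2D line-COM construction (mean of projected points) stays close
    #: to the projection of the 3D centroid under perspective; wider arcs
    #: shift the triangulated COM posteriorly by a constant few tenths mm.
    interface_span_deg: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.cap_height <= self.radius:
            raise ValueError("cap height must be in (0, radius]")
        apex_y = self.apex.y_si
        if any(m.y_si >= apex_y for m in self.markers):
            raise ValueError("markers must be inferior to the dome apex")

    def sphere_center(self) -> np.ndarray:
        return self.apex.as_array() - np.array([0.0, self.radius, 0.0])

    def interface_arc(self, n: int = 121) -> np.ndarray:
        """Dense material arc across the dome (ML-SI plane), for rendering.

        Includes the surface dimple; the idealized tracking points of
        ``interface_points`` stay on the smooth sphere (the anchor offsets
        recorded at template extraction absorb the constant difference).
        """
        theta_max = np.arccos((self.radius - self.cap_height) / self.radius)
        th = np.linspace(-theta_max, theta_max, n)
        c = self.sphere_center()
        r = self.radius - self.dimple_depth * np.exp(
            -0.5 * ((np.rad2deg(th) - self.dimple_theta_deg) / self.dimple_sigma_deg) ** 2
        )
        pts = np.stack(
            [
                c[0] + r * np.sin(th),
                c[1] + r * np.cos(th),
                np.full_like(th, c[2]),
            ],
            axis=1,
        )
        return pts

    def interface_points(self, n: int | None = None) -> np.ndarray:
        """Material points tracked as the diaphragm line (detection seeds).

        A sub-arc of the full interface (default +/-35 degrees about the
        apex) where the projected edge is well resolved on both imagers.
        The centroid of these points is the phantom's "diaphragm COM"
        ground truth.
        """
        n = n or self.n_interface_points
        half = np.deg2rad(self.interface_span_deg / 2.0)
        th = np.linspace(-half, half, n)
        c = self.sphere_center()
        return np.stack(
            [
                c[0] + self.radius * np.sin(th),
                c[1] + self.radius * np.cos(th),
                np.full_like(th, c[2]),
            ],
            axis=1,
        )

    def diaphragm_com(self) -> np.ndarray:
        """Rest position of the tracked diaphragm COM (mm, room frame)."""
        return self.interface_points().mean(axis=0)

    def marker_com(self) -> np.ndarray:
        return np.mean([m.as_array() for m in self.markers], axis=0)

    def marker_dome_si_distance(self) -> float:
        """SI distance (mm) from marker COM to the dome apex, cf. the
        17-82 mm per-patient range."""
        return float(self.apex.y_si - self.marker_com()[1])


def default_phantom(**overrides) -> DigitalPhantom:
    """The study-default phantom (markers ~38 mm inferior to the apex)."""
    return replace(DigitalPhantom(), **overrides) if overrides else DigitalPhantom()


@dataclass
class BreathingTrace:
    """Phase-linked internal (3D) and external (scalar) breathing signals.

    ``internal_displacement`` is the displacement of the moving anatomy from
    its rest position, per axis (ML, SI, AP), dominated by SI;
    ``external_signal`` is the AP displacement of the chest surrogate the IR
    camera sees. For the ``perturbed`` pattern the two are linked through a
    common respiratory phase with optional hysteresis lag, so the external
    signal leads/lags the internal one, producing the loop-shaped
    internal-vs-external curves of real patients.
    """

    times: np.ndarray
    internal_displacement: np.ndarray  # (n, 3) mm
    external_signal: np.ndarray  # (n,) mm
    pattern: str = "sinusoid"

    def displacement_at(self, t) -> np.ndarray:
        """Linear interpolation of the internal displacement at times t."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.stack(
            [np.interp(t, self.times, self.internal_displacement[:, k]) for k in range(3)],
            axis=1,
        )
        return out

    def external_at(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.times, self.external_signal)

    @property
    def si_peak_to_peak(self) -> float:
        y = self.internal_displacement[:, 1]
        return float(y.max() - y.min())


def make_breathing_trace(
    pattern: str = "sinusoid",
    amplitude_mm: float = 22.5,
    rate_bpm: float = 6.0,
    duration_s: float = 40.0,
    sample_hz: float = 25.0,
    ml_fraction: float = 0.0,
    ap_fraction: float = 0.0,
    external_gain: float = 0.4,
    amplitude_jitter: float = 0.0,
    period_jitter: float = 0.0,
    drift_mm_per_min: float = 0.0,
    hysteresis_lag_s: float = 0.0,
    external_noise_sd: float = 0.0,
    seed: int | None = None,
) -> BreathingTrace:
    """Generate a breathing trace.

    ``amplitude_mm`` is the SI peak-to-peak excursion (the motion platform's
    programmed 22.5 mm). ``rate_bpm`` is breaths per minute (6 BPM = 10 s
    period, so a 40 s acquisition covers four breathing cycles). ML/AP
    internal components are fixed fractions of the SI component (zero for
    the platform phantom, small nonzero values for patient-like motion).

    The ``perturbed`` pattern draws a fresh amplitude and period for every
    cycle (relative SDs ``amplitude_jitter`` / ``period_jitter``), adds a
    linear baseline drift, and applies ``hysteresis_lag_s`` between the
    external surrogate phase and the internal motion. Gaussian noise of SD
    ``external_noise_sd`` mm is added to the external channel only.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude must be >= 0")
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    if pattern not in ("sinusoid", "perturbed"):
        raise ValueError(f"unknown breathing pattern {pattern!r}")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_hz)) + 1
    t = np.arange(n) / sample_hz
    period = 60.0 / rate_bpm

    if pattern == "sinusoid":
        phase = 2.0 * np.pi * t / period
        half_amp = np.full(n, amplitude_mm / 2.0)
        drift = np.zeros(n)
        phase_ext = phase
    else:
        # Build cycle boundaries with jittered periods, then a continuous
        # phase by interpolation; amplitude envelope piecewise per cycle.
        n_cycles = int(np.ceil(duration_s / period)) + 3
        periods = period * np.clip(
            1.0 + period_jitter * rng.standard_normal(n_cycles), 0.3, 3.0
        )
        bounds = np.concatenate([[0.0], np.cumsum(periods)])
        cyc_amp = (amplitude_mm / 2.0) * np.clip(
            1.0 + amplitude_jitter * rng.standard_normal(n_cycles), 0.05, None
        )
        phase = 2.0 * np.pi * np.interp(t, bounds, np.arange(n_cycles + 1))
        # Anchor the amplitude envelope at mid-cycle (where the peak sits),
        # so each drawn amplitude is realized exactly at its cycle's peak.
        mids = 0.5 * (bounds[:-1] + bounds[1:])
        half_amp = np.interp(t, mids, cyc_amp)
        drift = (drift_mm_per_min / 60.0) * t
        phase_ext = 2.0 * np.pi * np.interp(
            t + hysteresis_lag_s, bounds, np.arange(n_cycles + 1)
        )

    # -cos: the trace starts at end-exhale (most inferior) and peaks mid-cycle.
    si = -half_amp * np.cos(phase) + drift
    internal = np.stack([ml_fraction * si, si, ap_fraction * si], axis=1)
    external = external_gain * (-half_amp * np.cos(phase_ext) + drift)
    if external_noise_sd > 0:
        external = external + external_noise_sd * rng.standard_normal(n)
    return BreathingTrace(
        times=t,
        internal_displacement=internal,
        external_signal=external,
        pattern=pattern,
    )


def patient_like_trace(
    duration_s: float = 130.0,
    amplitude_mm: float = 15.0,
    rate_bpm: float = 7.5,
    seed: int | None = None,
    **overrides,
) -> BreathingTrace:
    """A perturbed breathing trace with patient-scale irregularity.

    Defaults: 15 mm SI peak-to-peak at 7.5 breaths/min (an 8 s cycle, so a
    40 s model-building window spans ~5 cycles), with small ML/AP internal
    components, 8%/6% cycle-to-cycle amplitude/period jitter, slow baseline
    drift, a 0.3 s external-to-internal hysteresis lag, and measurement
    noise on the external channel. These are generator choices producing
    deviations of clinically reported magnitude, not values measured from
    any patient cohort.
    """
    kwargs = dict(
        pattern="perturbed",
        amplitude_mm=amplitude_mm,
        rate_bpm=rate_bpm,
        duration_s=duration_s,
        sample_hz=25.0,
        ml_fraction=0.10,
        ap_fraction=0.25,
        external_gain=0.4,
        amplitude_jitter=0.08,
        period_jitter=0.06,
        drift_mm_per_min=0.8,
        hysteresis_lag_s=0.3,
        external_noise_sd=0.05,
        seed=seed,
    )
    kwargs.update(overrides)
    return make_breathing_trace(**kwargs)


def _project_points(
    geom: ImagingGeometry, pts: np.ndarray, imager_id: str
) -> np.ndarray:
    """Project an (n, 3) array of room points; returns (n, 2) [u, v] px."""
    out = np.empty((len(pts), 2))
    for i, p in enumerate(pts):
        pc = project_point(geom, RoomPoint.from_array(p), imager_id)
        out[i] = (pc.u, pc.v)
    return out


def render_frame(
    phantom: DigitalPhantom,
    geom: ImagingGeometry,
    displacement: RoomPoint | np.ndarray,
    imager_id: str = "A",
    noise: NoiseParams = NoiseParams(),
    seed: int | None = None,
    time_s: float = 0.0,
    frame_id: int = 0,
) -> FluoroFrame:
    """Render one 16-bit fluoroscopy frame of the displaced phantom.

    The dome silhouette is drawn as a smooth intensity ramp (width
    ``phantom.edge_ramp_px``) along the projected interface arc; markers are
    elongated dark Gaussian blobs whose intensity centroid coincides with
    the forward-projected marker position. Gaussian noise and isolated
    extreme-valued dead pixels are then applied. Same seed, same frame —
    bit-identical.
    """
    disp = displacement.as_array() if isinstance(displacement, RoomPoint) else np.asarray(displacement, float)
    cols, rows = geom.matrix_px
    rng = np.random.default_rng(seed)

    # Interface curve in image space: project the dense material arc.
    arc = phantom.interface_arc() + disp
    uv = _project_points(geom, arc, imager_id)
    order = np.argsort(uv[:, 0])
    u_arc, v_arc = uv[order, 0], uv[order, 1]
    v_curve = np.interp(np.arange(cols, dtype=float), u_arc, v_arc)

    vgrid = np.arange(rows, dtype=float)[:, None]
    # Rows advance inferior: lung (bright) sits at v < v_curve.
    above = np.clip((v_curve[None, :] - vgrid) / phantom.edge_ramp_px + 0.5, 0.0, 1.0)
    img = LIVER_LEVEL + phantom.tissue_contrast * above

    # Markers: anisotropic Gaussian blobs (dark), FWHM set by the physical
    # seed size mapped to detector pixels at the isocenter-plane scale.
    pitch = geom.pixel_pitch
    sig_u = max(phantom.marker_size[0] / 2.355 / pitch, 0.8)
    sig_v = max(phantom.marker_size[1] / 2.355 / pitch, 0.8)
    half_u, half_v = int(np.ceil(5 * sig_u)), int(np.ceil(5 * sig_v))
    for m in phantom.markers:
        mpos = m.as_array() + phantom.marker_motion_scale * disp
        pc = project_point(geom, RoomPoint.from_array(mpos), imager_id)
        cu, cv = int(round(pc.u)), int(round(pc.v))
        u0, u1 = max(cu - half_u, 0), min(cu + half_u + 1, cols)
        v0, v1 = max(cv - half_v, 0), min(cv + half_v + 1, rows)
        if u0 >= u1 or v0 >= v1:
            continue
        uu = np.arange(u0, u1, dtype=float)[None, :] - pc.u
        vv = np.arange(v0, v1, dtype=float)[:, None] - pc.v
        blob = np.exp(-0.5 * ((uu / sig_u) ** 2 + (vv / sig_v) ** 2))
        img[v0:v1, u0:u1] -= MARKER_DEPTH * blob

    if noise.gaussian_sd > 0:
        img = img + noise.gaussian_sd * rng.standard_normal(img.shape)
    img = np.clip(img, 0, 65535)

    if noise.dead_pixels > 0:
        placed = _place_dead_pixels(rng, rows, cols, noise.dead_pixels)
        img[placed[:, 0], placed[:, 1]] = np.where(
            rng.random(len(placed)) < 0.5, 0.0, 65535.0
        )

    return FluoroFrame(
        pixels=img.astype(np.uint16),
        imager_id=imager_id,
        time_s=time_s,
        gantry_deg=geom.gantry_deg,
        ring_deg=geom.ring_deg,
        frame_id=frame_id,
    )


def _place_dead_pixels(rng, rows: int, cols: int, count: int) -> np.ndarray:
    """Draw `count` mutually isolated (no 8-adjacency) pixel locations."""
    chosen: list = []
    attempts = 0
    while len(chosen) < count and attempts < 100 * count:
        r = int(rng.integers(1, rows - 1))
        c = int(rng.integers(1, cols - 1))
        if all(max(abs(r - rr), abs(c - cc)) > 1 for rr, cc in chosen):
            chosen.append((r, c))
        attempts += 1
    return np.array(chosen, dtype=int).reshape(-1, 2)


#: Frame-timestamp policies mirroring the clinical workflow regimes.
FRAMERATE_POLICIES = {
    "model_building": 5.0,  # ~5 fps fluoroscopy over 20-40 s
    "verification": 1.0,  # ~1 Hz during gimbal-tracking verification
    "template": 5.0,  # short burst used to refresh detection templates
}
TEMPLATE_BURST_FRAMES = 13


@dataclass
class SimulatedSession:
    """A rendered dual-orthogonal fluoroscopy session with ground truth."""

    frames_a: FluoroSequence
    frames_b: FluoroSequence
    ir_trace: BreathingTrace
    truth_times: np.ndarray
    truth_diaphragm: np.ndarray  # (n, 3) mm, tracked diaphragm COM
    truth_markers: np.ndarray  # (n, 3) mm, marker COM
    truth_markers_individual: np.ndarray  # (n, 3 markers, 3) mm
    phantom: DigitalPhantom = field(default_factory=default_phantom)
    geom: ImagingGeometry = field(default_factory=ImagingGeometry)
    seed: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.frames_a)

    def frame_pairs(self):
        return zip(self.frames_a, self.frames_b)


def simulate_session(
    phantom: DigitalPhantom,
    geom: ImagingGeometry,
    trace: BreathingTrace,
    framerate_policy: str = "model_building",
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    duration_s: float | None = None,
    start_s: float = 0.0,
) -> SimulatedSession:
    """Render a paired-imager fluoroscopy session along a breathing trace.

    Timestamps follow the named policy: ``model_building`` (~5 fps over the
    trace duration), ``verification`` (~1 Hz), or ``template`` (a 13-frame
    burst at 5 fps, the short series used to refresh detection templates at
    each new beam angle). ``start_s`` offsets the acquisition within the
    trace (model building early, verification later, as in the clinical
    sequence). Ground-truth diaphragm-COM and marker-COM traces are
    recorded at every frame time.
    """
    if framerate_policy not in FRAMERATE_POLICIES:
        raise ValueError(f"unknown framerate policy {framerate_policy!r}")
    fps = FRAMERATE_POLICIES[framerate_policy]
    total = (duration_s if duration_s is not None
             else float(trace.times[-1]) - start_s)
    if start_s + total > trace.times[-1] + 1e-9:
        raise ValueError("breathing trace does not cover the requested duration")
    if framerate_policy == "template":
        times = start_s + np.arange(TEMPLATE_BURST_FRAMES) / fps
    else:
        times = np.arange(int(np.floor(total * fps)) + 1) / fps
        times = start_s + times[times <= total + 1e-9]

    ss = np.random.SeedSequence(seed)
    frame_seeds = ss.generate_state(2 * len(times))

    disp = trace.displacement_at(times)
    d_com = phantom.diaphragm_com()
    m_pts = np.array([m.as_array() for m in phantom.markers])
    truth_d = d_com[None, :] + disp
    truth_m_ind = m_pts[None, :, :] + phantom.marker_motion_scale * disp[:, None, :]
    truth_m = truth_m_ind.mean(axis=1)

    seq_a = FluoroSequence(imager_id=geom.imager_ids[0])
    seq_b = FluoroSequence(imager_id=geom.imager_ids[1])
    for i, t in enumerate(times):
        seq_a.frames.append(
            render_frame(
                phantom, geom, disp[i], geom.imager_ids[0], noise,
                seed=int(frame_seeds[2 * i]), time_s=float(t), frame_id=i,
            )
        )
        seq_b.frames.append(
            render_frame(
                phantom, geom, disp[i], geom.imager_ids[1], noise,
                seed=int(frame_seeds[2 * i + 1]), time_s=float(t), frame_id=i,
            )
        )
    return SimulatedSession(
        frames_a=seq_a,
        frames_b=seq_b,
        ir_trace=trace,
        truth_times=times,
        truth_diaphragm=truth_d,
        truth_markers=truth_m,
        truth_markers_individual=truth_m_ind,
        phantom=phantom,
        geom=geom,
        seed=seed,
    )
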