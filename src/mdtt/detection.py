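"""Structure detection on kV fluoroscopy frames.

Detection follows the clinical image-analysis chain: each raw 16-bit frame
is converted to a 256-level intensity image and median-filtered to suppress
dead pixels, then the diaphragm interface (a set of points on a line) and
the fiducial markers (single points) are located by normalized
cross-correlation (NCC) template matching with sub-pixel peak refinement.
Across a fluoroscopy sequence, detections are propagated frame-to-frame:
each frame's search windows are centered on the previous frame's positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.feature import match_template as _ncc_match

from .frames import FluoroFrame, FluoroSequence
from .geometry import PixelCoord

__all__ = [
    "Template",
    "Detection2D",
    "DiaphragmDetection",
    "DetectionConfig",
    "preprocess",
    "extract_template",
    "match_template",
    "detect_markers",
    "detect_diaphragm",
    "propagate_sequence",
    "SequenceDetections",
]


@dataclass(frozen=True)
class Template:
    """An NCC template patch with the tracked feature's sub-pixel anchor.

    ``anchor`` = (au, av) is the offset of the physical feature (marker
    center or diaphragm-line point) from the patch's top-left pixel center.
    """

    patch: np.ndarray
    anchor: tuple
    kind: str = "marker"  # or "diaphragm_point"

    def __post_init__(self) -> None:
        au, av = self.anchor
        h, w = self.patch.shape
        if not (0 <= au <= w - 1 and 0 <= av <= h - 1):
            raise ValueError("anchor must lie inside the patch")


@dataclass(frozen=True)
class Detection2D:
    """A sub-pixel 2D detection with its NCC peak score."""

    position: PixelCoord
    score: float
    kind: str
    frame_time: float = 0.0
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.score <= 1.0 + 1e-9:
            raise ValueError("NCC score must lie in [-1, 1]")


@dataclass
class DiaphragmDetection:
    """Per-frame diaphragm line detections and their center of mass."""

    points: list
    com: PixelCoord | None
    valid: bool


@dataclass(frozen=True)
class DetectionConfig:
    """Tunables for template matching and propagation.

    ``search_half_width`` (px) is the half-size of the window centered on
    the propagated prior: per-frame motion at ~5 fps is only a few pixels,
    so the default 20 px leaves a wide margin. Detections whose peak NCC
    falls below ``min_score`` are flagged low-confidence (kept, never
    silently dropped); ``max_lost_frames`` consecutive low-confidence
    frames flag the whole sequence.
    """

    template_half_size: int = 10
    search_half_width: int = 20
    min_score: float = 0.5
    min_diaphragm_points: int = 3
    max_lost_frames: int = 5
    median_filter_size: int = 3
    #: Half-width (px) of the column band for diaphragm-line points. The
    #: interface is smooth along its own direction, so an unconstrained 2D
    #: search slides tangentially along the edge; banding the window in u
    #: pins each line point to its column while leaving the full vertical
    #: search. 0 = strict fixed-column tracking (interface height only).
    diaphragm_u_band: int = 0
    #: Diaphragm lateral-tracking mode. False (default): line points keep
    #: their seeded columns and only their vertical position is tracked —
    #: exact for SI-dominant motion and free of the tangential ambiguity of
    #: a smooth edge. True: a wide template spanning the whole interface
    #: arc first estimates the structure's global 2D shift per frame (its
    #: overall curvature and surface features localize the along-edge
    #: direction), and the column bands ride on that shift; this follows
    #: ML/AP motion at the cost of a few tenths mm lateral noise.
    track_lateral: bool = False


def preprocess(frame: FluoroFrame | np.ndarray, median_size: int = 3) -> np.ndarray:
    """Rescale to 256 gray levels and median-filter out dead pixels.

    The raw 16-bit raster is linearly mapped (min -> 0, max -> 255, a
    constant image maps to all zeros), quantized to integer gray levels,
    then passed through a median filter (reflected edges). Returns float64.
    """
    px = frame.pixels if isinstance(frame, FluoroFrame) else frame
    px = np.asarray(px, dtype=float)
    lo, hi = px.min(), px.max()
    if hi > lo:
        g = np.floor((px - lo) / (hi - lo) * 255.0).clip(0, 255)
    else:
        g = np.zeros_like(px)
    return ndimage.median_filter(g, size=median_size, mode="reflect")


def extract_template(
    image: np.ndarray, center: PixelCoord, half_size: int = 10, kind: str = "marker"
) -> Template:
    """Cut a (2h+1)-square template around a feature position.

    The anchor records the feature's sub-pixel offset within the patch, so
    detections report the feature position, not the patch corner.
    """
    cu, cv = int(round(center.u)), int(round(center.v))
    h, w = image.shape
    u0, v0 = cu - half_size, cv - half_size
    u1, v1 = cu + half_size + 1, cv + half_size + 1
    if u0 < 0 or v0 < 0 or u1 > w or v1 > h:
        raise ValueError("template window exceeds image bounds")
    patch = image[v0:v1, u0:u1].copy()
    return Template(patch=patch, anchor=(center.u - u0, center.v - v0), kind=kind)


def _parabolic_offset(sm1: float, s0: float, sp1: float) -> float:
    """Sub-pixel offset of a quadratic through three samples; clamped to
    +/-0.5 px so refinement can never leave the argmax pixel."""
    denom = sm1 - 2.0 * s0 + sp1
    if denom >= 0 or abs(denom) < 1e-12:  # flat or non-concave
        return 0.0
    return float(np.clip(0.5 * (sm1 - sp1) / denom, -0.5, 0.5))


def match_template(
    image: np.ndarray,
    template: Template,
    search_window: tuple | None = None,
    frame_time: float = 0.0,
    imager_id: str = "A",
) -> Detection2D:
    """NCC template match within a window, with sub-pixel refinement.

    ``search_window`` is (u_min, u_max, v_min, v_max) in pixel indices
    (inclusive-exclusive); None searches the whole image. The integer
    argmax of the normalized cross-correlation map is refined independently
    per axis by a parabolic fit to the 3x3 score neighborhood.

    Raises
    ------
    ValueError
        If the window is smaller than the template, or the windowed image
        is constant (NCC undefined).
    """
    h, w = image.shape
    if search_window is None:
        u0, u1, v0, v1 = 0, w, 0, h
    else:
        u0, u1, v0, v1 = search_window
        u0, v0 = max(int(u0), 0), max(int(v0), 0)
        u1, v1 = min(int(u1), w), min(int(v1), h)
    sub = image[v0:v1, u0:u1]
    th, tw = template.patch.shape
    if sub.shape[0] < th or sub.shape[1] < tw:
        raise ValueError("search window smaller than template")
    if np.ptp(sub) == 0:
        raise ValueError("constant search window: NCC undefined")
    scores = _ncc_match(sub.astype(float), template.patch.astype(float))
    iv, iu = np.unravel_index(np.argmax(scores), scores.shape)
    peak = float(scores[iv, iu])

    du = dv = 0.0
    if 0 < iu < scores.shape[1] - 1:
        du = _parabolic_offset(scores[iv, iu - 1], peak, scores[iv, iu + 1])
    if 0 < iv < scores.shape[0] - 1:
        dv = _parabolic_offset(scores[iv - 1, iu], peak, scores[iv + 1, iu])

    au, av = template.anchor
    pos = PixelCoord(u=u0 + iu + du + au, v=v0 + iv + dv + av, imager_id=imager_id)
    return Detection2D(
        position=pos,
        score=min(max(peak, -1.0), 1.0),
        kind=template.kind,
        frame_time=frame_time,
    )


def _window_around(pc: PixelCoord, half: int) -> tuple:
    return (
        int(round(pc.u)) - half,
        int(round(pc.u)) + half + 1,
        int(round(pc.v)) - half,
        int(round(pc.v)) + half + 1,
    )


def detect_markers(
    frame: FluoroFrame,
    templates: list,
    prior_positions: list,
    config: DetectionConfig = DetectionConfig(),
    image: np.ndarray | None = None,
) -> list:
    """Detect each fiducial marker near its propagated prior position.

    One template and one prior per marker. A peak below ``min_score`` (or a
    window that degenerates at the image edge) yields a low-confidence
    detection at the prior position rather than a silent drop.
    """
    if len(templates) != len(prior_positions):
        raise ValueError("need one prior position per template")
    img = preprocess(frame, config.median_filter_size) if image is None else image
    half = config.search_half_width + config.template_half_size
    out = []
    for tmpl, prior in zip(templates, prior_positions):
        try:
            det = match_template(
                img, tmpl, _window_around(prior, half),
                frame_time=frame.time_s, imager_id=frame.imager_id,
            )
            if det.score < config.min_score:
                det = replace(det, low_confidence=True)
        except ValueError:
            det = Detection2D(
                position=PixelCoord(prior.u, prior.v, frame.imager_id),
                score=0.0,
                kind=tmpl.kind,
                frame_time=frame.time_s,
                low_confidence=True,
            )
        out.append(det)
    return out


def detect_diaphragm(
    frame: FluoroFrame,
    templates: list,
    prior_positions: list,
    config: DetectionConfig = DetectionConfig(),
    image: np.ndarray | None = None,
) -> DiaphragmDetection:
    """Detect the diaphragm-line points and their 2D center of mass.

    Each interface point is matched in a column-banded window: narrow
    (``diaphragm_u_band``) around the prior column, full search height
    vertically. The unweighted mean of the confident detections is the
    frame's 2D diaphragm COM. Fewer than ``min_diaphragm_points`` confident
    points marks the frame invalid for 3D reconstruction.
    """
    if len(templates) < config.min_diaphragm_points:
        raise ValueError(
            f"need at least {config.min_diaphragm_points} diaphragm point templates"
        )
    img = preprocess(frame, config.median_filter_size) if image is None else image
    half_v = config.search_half_width + config.template_half_size
    half_u = config.diaphragm_u_band + config.template_half_size
    dets = []
    for tmpl, prior in zip(templates, prior_positions):
        window = (
            int(round(prior.u)) - half_u, int(round(prior.u)) + half_u + 1,
            int(round(prior.v)) - half_v, int(round(prior.v)) + half_v + 1,
        )
        try:
            det = match_template(img, tmpl, window, frame_time=frame.time_s,
                                 imager_id=frame.imager_id)
            if det.score < config.min_score:
                det = replace(det, low_confidence=True)
        except ValueError:
            det = Detection2D(
                position=PixelCoord(prior.u, prior.v, frame.imager_id),
                score=0.0, kind=tmpl.kind, frame_time=frame.time_s,
                low_confidence=True,
            )
        dets.append(det)
    good = [d for d in dets if not d.low_confidence]
    if len(good) < config.min_diaphragm_points:
        return DiaphragmDetection(points=dets, com=None, valid=False)
    com = PixelCoord(
        u=float(np.mean([d.position.u for d in good])),
        v=float(np.mean([d.position.v for d in good])),
        imager_id=frame.imager_id,
    )
    return DiaphragmDetection(points=dets, com=com, valid=True)


@dataclass
class SequenceDetections:
    """Per-frame detections for one imager across a fluoroscopy sequence."""

    times: np.ndarray
    marker_detections: list  # per frame: list of Detection2D
    diaphragm: list  # per frame: DiaphragmDetection
    imager_id: str = "A"
    lost: bool = False  # propagation lost for >= max_lost_frames

    @property
    def n_invalid(self) -> int:
        return sum(0 if d.valid else 1 for d in self.diaphragm)


def _line_template(image: np.ndarray, seeds: list, config: DetectionConfig) -> Template:
    """One wide template spanning the whole diaphragm line.

    Individual line-point patches see a locally smooth edge and cannot
    resolve motion along the interface; the full arc has enough curvature
    (several pixels of sagitta across its width) to pin down the global 2D
    shift of the structure, which then carries the per-point column bands.
    """
    us = [p.u for p in seeds]
    vs = [p.v for p in seeds]
    cu, cv = float(np.mean(us)), float(np.mean(vs))
    half_u = int(np.ceil((max(us) - min(us)) / 2)) + config.template_half_size
    half_v = int(np.ceil((max(vs) - min(vs)) / 2)) + config.template_half_size
    h, w = image.shape
    u0 = int(round(cu)) - half_u
    v0 = int(round(cv)) - half_v
    u1, v1 = u0 + 2 * half_u + 1, v0 + 2 * half_v + 1
    if u0 < 0 or v0 < 0 or u1 > w or v1 > h:
        raise ValueError("diaphragm line template exceeds image bounds")
    return Template(
        patch=image[v0:v1, u0:u1].copy(),
        anchor=(cu - u0, cv - v0),
        kind="diaphragm_line",
    )


def propagate_sequence(
    sequence: FluoroSequence,
    marker_templates: list,
    marker_seeds: list,
    diaphragm_templates: list,
    diaphragm_seeds: list,
    config: DetectionConfig = DetectionConfig(),
    seed_image: np.ndarray | None = None,
) -> SequenceDetections:
    """Track all structures through a sequence by windowed NCC propagation.

    Frame t's search windows are centered on frame t-1's detections
    (low-confidence detections propagate the prior instead, so a brief loss
    does not derail the track). Templates are taken from the seeding frame
    and held fixed.

    The diaphragm is tracked according to ``config.track_lateral``: in the
    default fixed-column mode each line point keeps its seeded column and
    only its vertical position propagates; in lateral mode a wide template
    covering the whole interface arc first locates the structure's global
    2D shift, and the column bands ride on that shift. The sequence is
    flagged ``lost`` when any structure stays low-confidence for
    ``max_lost_frames`` consecutive frames.
    """
    m_prior = list(marker_seeds)
    d_prior = list(diaphragm_seeds)
    line_tmpl = None
    line_prior = line_com0 = None
    if config.track_lateral:
        img0 = (seed_image if seed_image is not None
                else preprocess(sequence[0], config.median_filter_size))
        line_tmpl = _line_template(img0, diaphragm_seeds, config)
        line_com0 = PixelCoord(
            float(np.mean([p.u for p in diaphragm_seeds])),
            float(np.mean([p.v for p in diaphragm_seeds])),
            sequence.imager_id,
        )
        line_prior = line_com0

    marker_out, diaphragm_out, times = [], [], []
    lost_run = 0
    lost = False
    for frame in sequence:
        img = preprocess(frame, config.median_filter_size)
        m_dets = detect_markers(frame, marker_templates, m_prior, config, image=img)

        if config.track_lateral:
            # Stage 1: global shift of the interface from the wide template.
            th, tw = line_tmpl.patch.shape
            half_u = config.search_half_width + tw // 2
            half_v = config.search_half_width + th // 2
            window = (
                int(round(line_prior.u)) - half_u,
                int(round(line_prior.u)) + half_u + 1,
                int(round(line_prior.v)) - half_v,
                int(round(line_prior.v)) + half_v + 1,
            )
            try:
                line_det = match_template(img, line_tmpl, window,
                                          frame_time=frame.time_s,
                                          imager_id=frame.imager_id)
                line_ok = line_det.score >= config.min_score
            except ValueError:
                line_det = None
                line_ok = False
            if line_ok:
                shift_u = line_det.position.u - line_com0.u
                shift_v = line_det.position.v - line_com0.v
            else:
                shift_u = line_prior.u - line_com0.u
                shift_v = line_prior.v - line_com0.v
            # Stage 2: vertical refinement in shifted column bands.
            d_prior = [
                PixelCoord(s.u + shift_u, s.v + shift_v, frame.imager_id)
                for s in diaphragm_seeds
            ]
            d_det = detect_diaphragm(frame, diaphragm_templates, d_prior, config,
                                     image=img)
            if not line_ok:
                d_det = DiaphragmDetection(points=d_det.points, com=d_det.com,
                                           valid=False)
            if line_ok:
                line_prior = line_det.position
        else:
            d_det = detect_diaphragm(frame, diaphragm_templates, d_prior, config,
                                     image=img)
            # Fixed columns: propagate the vertical position only.
            d_prior = [
                PixelCoord(seed.u, det.position.v, frame.imager_id)
                if not det.low_confidence else prior
                for det, prior, seed in zip(d_det.points, d_prior, diaphragm_seeds)
            ]

        marker_out.append(m_dets)
        diaphragm_out.append(d_det)
        times.append(frame.time_s)

        m_prior = [
            det.position if not det.low_confidence else prior
            for det, prior in zip(m_dets, m_prior)
        ]
        any_low = any(d.low_confidence for d in m_dets) or not d_det.valid
        lost_run = lost_run + 1 if any_low else 0
        if lost_run >= config.max_lost_frames:
            lost = True
    return SequenceDetections(
        times=np.array(times),
        marker_detections=marker_out,
        diaphragm=diaphragm_out,
        imager_id=sequence.imager_id,
        lost=lost,
    )


def seed_from_truth(session, imager_id: str, config: DetectionConfig = DetectionConfig()):
    """Build templates and seed positions from a simulated session's truth.

    Stands in for the clinical manual-alignment step in which the user
    drags the projected contour overlay onto the first image pair: here the
    forward-projected ground-truth positions of frame 0 seed the tracker.
    Returns (marker_templates, marker_seeds, diaphragm_templates,
    diaphragm_seeds).
    """
    from .geometry import RoomPoint, project_point

    seq = session.frames_a if imager_id == session.geom.imager_ids[0] else session.frames_b
    frame0 = seq[0]
    img0 = preprocess(frame0, config.median_filter_size)
    disp0 = session.ir_trace.displacement_at(frame0.time_s)[0]

    marker_seeds, diaphragm_seeds = [], []
    for m in session.phantom.markers:
        p = m.as_array() + session.phantom.marker_motion_scale * disp0
        marker_seeds.append(project_point(session.geom, RoomPoint.from_array(p), imager_id))
    for p in session.phantom.interface_points() + disp0:
        diaphragm_seeds.append(project_point(session.geom, RoomPoint.from_array(p), imager_id))

    marker_templates = [
        extract_template(img0, pc, config.template_half_size, kind="marker")
        for pc in marker_seeds
    ]
    diaphragm_templates = [
        extract_template(img0, pc, config.template_half_size, kind="diaphragm_point")
        for pc in diaphragm_seeds
    ]
    return marker_templates, marker_seeds, diaphragm_templates, diaphragm_seeds
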