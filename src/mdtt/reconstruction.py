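"""3D motion-trace reconstruction from paired 2D detections.

Each simultaneously acquired image pair gives two detector positions of the
same structure; back-projecting both toward their kV sources and taking the
closest-approach point of the two rays localizes the structure in 3D at the
isocenter region. For the fiducial set, each marker is triangulated
separately and the three 3D points are averaged into the marker COM (exact
in the noiseless limit, unlike averaging in 2D first, which mixes
perspective scales). For the diaphragm, the per-imager 2D line COMs are
triangulated directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import SequenceDetections
from .geometry import ImagingGeometry, Intersection3D, backproject_ray, intersect_rays

__all__ = [
    "MotionTrace3D",
    "TraceComparison",
    "triangulate",
    "reconstruct_trace",
    "reconstruct_session",
    "compare_traces",
]

#: A/B frames are treated as simultaneous when their timestamps differ by
#: less than this (s); the simulator emits exact pairs, real logs may jitter.
PAIR_TIME_TOL = 1e-3

#: Ray closest-approach distance (mm) above which a reconstructed point is
#: flagged as geometrically inconsistent.
RESIDUAL_FLAG_MM = 2.0


@dataclass
class MotionTrace3D:
    """Time series of 3D positions (mm, ML/SI/AP room frame) at isocenter."""

    times: np.ndarray
    positions: np.ndarray  # (n, 3)
    structure: str = "diaphragm"  # or "markers"
    residuals: np.ndarray | None = None  # (n,) mm ray closest-approach
    flags: np.ndarray | None = None  # (n,) bool, residual above threshold

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.positions.shape != (len(self.times), 3):
            raise ValueError("times (n,) and positions (n, 3) required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def si_peak_to_peak(self) -> float:
        return float(np.ptp(self.positions[:, 1]))


@dataclass
class TraceComparison:
    """Per-axis absolute-difference statistics between two 3D traces."""

    abs_diff: np.ndarray  # (n, 3) mm
    mean: np.ndarray  # (3,) mean absolute deviation per axis
    sd: np.ndarray  # (3,) SD (n-1) of the absolute differences
    n: int
    centered: bool = False


def triangulate(
    geom: ImagingGeometry, pc_a, pc_b
) -> Intersection3D:
    """Back-project a detector-coordinate pair and intersect the rays."""
    return intersect_rays(backproject_ray(geom, pc_a), backproject_ray(geom, pc_b))


def reconstruct_trace(
    det_a: SequenceDetections,
    det_b: SequenceDetections,
    geom: ImagingGeometry,
    structure: str = "diaphragm",
    residual_flag_mm: float = RESIDUAL_FLAG_MM,
) -> MotionTrace3D:
    """Reconstruct one structure's 3D motion trace from paired detections.

    Frames are paired by timestamp (tolerance 1 ms); unpaired or invalid
    frames are skipped. ``structure`` selects the diaphragm line COM or the
    fiducial marker COM. The stored residual is the (mean, over markers)
    ray closest-approach distance; points above ``residual_flag_mm`` are
    flagged but kept.
    """
    if structure not in ("diaphragm", "markers"):
        raise ValueError(f"unknown structure {structure!r}")
    times, positions, residuals, flags = [], [], [], []
    jb = 0
    for ia, ta in enumerate(det_a.times):
        # advance B pointer to the matching timestamp
        while jb < len(det_b.times) and det_b.times[jb] < ta - PAIR_TIME_TOL:
            jb += 1
        if jb >= len(det_b.times) or abs(det_b.times[jb] - ta) > PAIR_TIME_TOL:
            continue  # unpaired frame
        if structure == "diaphragm":
            da, db = det_a.diaphragm[ia], det_b.diaphragm[jb]
            if not (da.valid and db.valid):
                continue
            hit = triangulate(geom, da.com, db.com)
            pos, res = hit.point.as_array(), hit.residual
        else:
            ma, mb = det_a.marker_detections[ia], det_b.marker_detections[jb]
            if len(ma) != len(mb):
                continue
            if any(d.low_confidence for d in ma + mb):
                continue
            pts, rs = [], []
            for da_m, db_m in zip(ma, mb):
                hit = triangulate(geom, da_m.position, db_m.position)
                pts.append(hit.point.as_array())
                rs.append(hit.residual)
            pos, res = np.mean(pts, axis=0), float(np.mean(rs))
        times.append(ta)
        positions.append(pos)
        residuals.append(res)
        flags.append(res > residual_flag_mm)
    return MotionTrace3D(
        times=np.array(times),
        positions=np.array(positions).reshape(-1, 3),
        structure=structure,
        residuals=np.array(residuals),
        flags=np.array(flags, dtype=bool),
    )


def reconstruct_session(session, config=None):
    """Run truth-seeded detection + reconstruction on a simulated session.

    Convenience wrapper over ``seed_from_truth`` -> ``propagate_sequence``
    -> ``reconstruct_trace``; returns (diaphragm_trace, marker_trace).
    """
    from .detection import DetectionConfig, propagate_sequence, seed_from_truth

    config = config or DetectionConfig()
    traces = {}
    dets = {}
    for seq, imager in ((session.frames_a, session.geom.imager_ids[0]),
                        (session.frames_b, session.geom.imager_ids[1])):
        mt, ms, dt, dsd = seed_from_truth(session, imager, config)
        dets[imager] = propagate_sequence(seq, mt, ms, dt, dsd, config)
    a, b = session.geom.imager_ids
    traces["diaphragm"] = reconstruct_trace(dets[a], dets[b], session.geom, "diaphragm")
    traces["markers"] = reconstruct_trace(dets[a], dets[b], session.geom, "markers")
    return traces["diaphragm"], traces["markers"]


def compare_traces(
    diaphragm: MotionTrace3D,
    markers: MotionTrace3D,
    center: bool = False,
) -> TraceComparison:
    """Per-axis absolute differences between two 3D motion traces.

    Timestamps are inner-joined (1 ms tolerance). With ``center=False`` the
    raw position differences are compared (two identical traces give zero;
    a constant offset appears fully in the mean). With ``center=True`` each
    trace is first reduced to its displacement about its own time-mean,
    which is the relevant comparison when the two structures sit at
    different anatomical locations (markers centimeters inferior to the
    dome) and only their *motion* is in question.

    Means and SDs use the absolute-difference series; SD uses the n-1
    denominator. Symmetric in its arguments.
    """
    ia, ib = [], []
    jb = 0
    for i, t in enumerate(diaphragm.times):
        while jb < len(markers.times) and markers.times[jb] < t - PAIR_TIME_TOL:
            jb += 1
        if jb < len(markers.times) and abs(markers.times[jb] - t) <= PAIR_TIME_TOL:
            ia.append(i)
            ib.append(jb)
    if not ia:
        raise ValueError("traces share no timestamps")
    pa = diaphragm.positions[ia]
    pb = markers.positions[ib]
    if center:
        pa = pa - pa.mean(axis=0)
        pb = pb - pb.mean(axis=0)
    ad = np.abs(pa - pb)
    n = len(ad)
    return TraceComparison(
        abs_diff=ad,
        mean=ad.mean(axis=0),
        sd=ad.std(axis=0, ddof=1) if n > 1 else np.zeros(3),
        n=n,
        centered=center,
    )
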