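"""File I/O and run configuration.

Everything the pipeline writes is plain text or standard raster formats:
frames as 16-bit TIFF (PNG accepted on read), tabular data as CSV (UTF-8,
header row, '.' decimal, units embedded in column names), configuration and
fitted models as YAML. All coordinates in files are mm in the (ML, SI, AP)
room frame; times are seconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .correlation import CorrelationModel
from .frames import FluoroFrame, FluoroSequence
from .geometry import ImagingGeometry
from .phantom import DigitalPhantom, NoiseParams, RoomPoint
from .reconstruction import MotionTrace3D

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_session",
    "read_session_frames",
    "write_trace",
    "read_trace",
    "write_detections",
    "write_tracking_log",
    "save_model",
    "load_model",
]


def _check_keys(d: dict, allowed, context: str) -> None:
    unknown = set(d) - set(allowed)
    if unknown:
        raise ValueError(f"unknown {context} config keys: {sorted(unknown)}")


@dataclass
class RunConfig:
    """A full pipeline run description (serializable, unknown keys rejected).

    Blocks mirror the pipeline stages: imaging geometry, phantom anatomy,
    breathing trace, image noise, detection tunables, correlation model /
    gating, margin coefficients. A run's config is echoed into its output
    directory so results are reproducible from config + seed alone.
    """

    geometry: dict = field(default_factory=dict)
    phantom: dict = field(default_factory=dict)
    trace: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    margins: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "mdtt_run"

    _GEOM_KEYS = ("sad_mm", "imager_offsets_deg", "field_at_iso_mm", "matrix_px",
                  "gantry_deg", "ring_deg")
    _PHANTOM_KEYS = ("apex_mm", "radius_mm", "cap_height_mm", "markers_mm",
                     "marker_size_mm", "marker_motion_scale", "n_interface_points",
                     "interface_span_deg")
    _TRACE_KEYS = ("pattern", "amplitude_mm", "rate_bpm", "duration_s", "sample_hz",
                   "ml_fraction", "ap_fraction", "external_gain", "amplitude_jitter",
                   "period_jitter", "drift_mm_per_min", "hysteresis_lag_s",
                   "external_noise_sd")
    _NOISE_KEYS = ("gaussian_sd", "dead_pixels")
    _DET_KEYS = ("template_half_size", "search_half_width", "min_score",
                 "min_diaphragm_points", "max_lost_frames", "median_filter_size")
    _MODEL_KEYS = ("tolerance_mm",)
    _MARGIN_KEYS = ("k_sys", "k_rand")

    def __post_init__(self) -> None:
        _check_keys(self.geometry, self._GEOM_KEYS, "geometry")
        _check_keys(self.phantom, self._PHANTOM_KEYS, "phantom")
        _check_keys(self.trace, self._TRACE_KEYS, "trace")
        _check_keys(self.noise, self._NOISE_KEYS, "noise")
        _check_keys(self.detection, self._DET_KEYS, "detection")
        _check_keys(self.model, self._MODEL_KEYS, "model")
        _check_keys(self.margins, self._MARGIN_KEYS, "margins")

    # -- builders ---------------------------------------------------------
    def build_geometry(self) -> ImagingGeometry:
        g = self.geometry
        return ImagingGeometry(
            sad=g.get("sad_mm", 1000.0),
            imager_offsets_deg=tuple(g.get("imager_offsets_deg", (45.0, -45.0))),
            field_at_iso=tuple(g.get("field_at_iso_mm", (216.0, 162.0))),
            matrix_px=tuple(g.get("matrix_px", (1024, 768))),
            gantry_deg=g.get("gantry_deg", 0.0),
            ring_deg=g.get("ring_deg", 0.0),
        )

    def build_phantom(self) -> DigitalPhantom:
        p = dict(self.phantom)
        kwargs = {}
        if "apex_mm" in p:
            kwargs["apex"] = RoomPoint(*p["apex_mm"])
        if "markers_mm" in p:
            kwargs["markers"] = tuple(RoomPoint(*m) for m in p["markers_mm"])
        for src, dst in (("radius_mm", "radius"), ("cap_height_mm", "cap_height"),
                         ("marker_size_mm", "marker_size"),
                         ("marker_motion_scale", "marker_motion_scale"),
                         ("n_interface_points", "n_interface_points"),
                         ("interface_span_deg", "interface_span_deg")):
            if src in p:
                kwargs[dst] = tuple(p[src]) if src == "marker_size_mm" else p[src]
        return DigitalPhantom(**kwargs)

    def build_noise(self) -> NoiseParams:
        return NoiseParams(**self.noise) if self.noise else NoiseParams()

    def build_detection_config(self):
        from .detection import DetectionConfig

        return DetectionConfig(**self.detection) if self.detection else DetectionConfig()

    def trace_kwargs(self) -> dict:
        return dict(self.trace)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Read a YAML run config; unknown keys anywhere are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    _check_keys(raw, allowed, "top-level")
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# -- sessions -------------------------------------------------------------

def write_session(session, out_dir) -> Path:
    """Write a simulated session: TIFF frames, manifest, IR + truth traces.

    Layout: ``frames/<imager>_<frame_id>.tif``, ``manifest.csv``
    (frame_id, imager_id, time_s, gantry_deg, ring_deg, file),
    ``ir_trace.csv``, ``truth_diaphragm.csv``, ``truth_markers.csv``.
    """
    import tifffile

    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    rows = []
    for seq in (session.frames_a, session.frames_b):
        for fr in seq:
            name = f"frames/{fr.imager_id}_{fr.frame_id:05d}.tif"
            tifffile.imwrite(out / name, fr.pixels)
            rows.append(
                dict(frame_id=fr.frame_id, imager_id=fr.imager_id,
                     time_s=fr.time_s, gantry_deg=fr.gantry_deg,
                     ring_deg=fr.ring_deg, file=name)
            )
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    tr = session.ir_trace
    pd.DataFrame({"time_s": tr.times, "signal_mm": tr.external_signal}).to_csv(
        out / "ir_trace.csv", index=False
    )
    for name, arr in (("truth_diaphragm", session.truth_diaphragm),
                      ("truth_markers", session.truth_markers)):
        pd.DataFrame(
            {"time_s": session.truth_times, "x_ml_mm": arr[:, 0],
             "y_si_mm": arr[:, 1], "z_ap_mm": arr[:, 2]}
        ).to_csv(out / f"{name}.csv", index=False)
    return out


def read_session_frames(session_dir) -> dict:
    """Read frames back per imager from a session directory's manifest."""
    import imageio.v3 as iio

    d = Path(session_dir)
    manifest = pd.read_csv(d / "manifest.csv")
    sequences: dict = {}
    for _, r in manifest.sort_values(["imager_id", "frame_id"]).iterrows():
        fr = FluoroFrame(
            pixels=np.asarray(iio.imread(d / r["file"])),
            imager_id=str(r["imager_id"]),
            time_s=float(r["time_s"]),
            gantry_deg=float(r["gantry_deg"]),
            ring_deg=float(r["ring_deg"]),
            frame_id=int(r["frame_id"]),
        )
        sequences.setdefault(fr.imager_id, FluoroSequence(imager_id=fr.imager_id))
        sequences[fr.imager_id].frames.append(fr)
    return sequences


# -- traces, detections, logs --------------------------------------------

def write_trace(trace: MotionTrace3D, path) -> None:
    df = pd.DataFrame(
        {"time_s": trace.times, "x_ml_mm": trace.positions[:, 0],
         "y_si_mm": trace.positions[:, 1], "z_ap_mm": trace.positions[:, 2]}
    )
    df["residual_mm"] = trace.residuals if trace.residuals is not None else np.nan
    df["structure"] = trace.structure
    df["flag"] = trace.flags if trace.flags is not None else False
    df.to_csv(path, index=False)


def read_trace(path) -> MotionTrace3D:
    df = pd.read_csv(path)
    return MotionTrace3D(
        times=df["time_s"].to_numpy(),
        positions=df[["x_ml_mm", "y_si_mm", "z_ap_mm"]].to_numpy(),
        structure=str(df["structure"].iloc[0]) if len(df) else "diaphragm",
        residuals=df["residual_mm"].to_numpy(),
        flags=df["flag"].to_numpy(dtype=bool),
    )


def write_detections(det_by_imager: dict, path) -> None:
    """Detections CSV: frame_id, imager_id, time_s, kind, marker_index,
    u_px, v_px, score, flag."""
    rows = []
    for imager_id, dets in det_by_imager.items():
        for fi, t in enumerate(dets.times):
            for mi, d in enumerate(dets.marker_detections[fi]):
                rows.append(dict(frame_id=fi, imager_id=imager_id, time_s=t,
                                 kind="marker", marker_index=mi,
                                 u_px=d.position.u, v_px=d.position.v,
                                 score=d.score, flag=d.low_confidence))
            dd = dets.diaphragm[fi]
            for pi, d in enumerate(dd.points):
                rows.append(dict(frame_id=fi, imager_id=imager_id, time_s=t,
                                 kind="diaphragm_point", marker_index=pi,
                                 u_px=d.position.u, v_px=d.position.v,
                                 score=d.score, flag=d.low_confidence))
    pd.DataFrame(rows).to_csv(path, index=False)


def write_tracking_log(records, states_by_time: dict, geom, path) -> None:
    """Tracking log CSV mirroring a treatment-log layout: surrogate state,
    detected and predicted positions, 3D difference, beam status."""
    rows = []
    for r in records:
        st = states_by_time.get(round(r.time_s, 6))
        rows.append(dict(
            time_s=r.time_s,
            signal_mm=st.signal_mm if st else np.nan,
            velocity_mm_s=st.velocity_mm_s if st else np.nan,
            det_x_mm=r.detected[0], det_y_mm=r.detected[1], det_z_mm=r.detected[2],
            pred_x_mm=r.predicted[0], pred_y_mm=r.predicted[1], pred_z_mm=r.predicted[2],
            vector_diff_mm=r.vector_diff_mm,
            gantry_deg=geom.gantry_deg, ring_deg=geom.ring_deg,
            beam_status=r.beam_status,
        ))
    pd.DataFrame(rows).to_csv(path, index=False)


def save_model(model: CorrelationModel, path) -> None:
    doc = {
        "form": "pos_axis = a0 + a1*s + a2*s^2 + b1*v",
        "axes": ["ml", "si", "ap"],
        "coefficients": [[float(c) for c in row] for row in model.coeffs],
        "signal_range_mm": [float(x) for x in model.signal_range],
        "velocity_range_mm_s": [float(x) for x in model.velocity_range],
        "residual_mean_mm": [float(x) for x in model.residual_mean],
        "residual_sd_mm": [float(x) for x in model.residual_sd],
        "n_fit": int(model.n_fit),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path) -> CorrelationModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return CorrelationModel(
        coeffs=np.array(doc["coefficients"], dtype=float),
        signal_range=tuple(doc["signal_range_mm"]),
        velocity_range=tuple(doc["velocity_range_mm_s"]),
        residual_mean=np.array(doc["residual_mean_mm"]),
        residual_sd=np.array(doc["residual_sd_mm"]),
        n_fit=doc.get("n_fit", 0),
    )
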