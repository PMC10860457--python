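"""Respiratory correlation model: external IR surrogate -> internal 3D position.

During the model-building fluoroscopy sequence (~5 fps over 20-40 s, about
four breathing cycles) the internal tracking-structure position is detected
on image pairs while the external IR chest signal is recorded. A per-axis
regression links the two so that, between imaging samples, the treatment
beam can follow the target from the external signal alone. During delivery,
low-rate (~1 Hz) verification images compare the detected position against
the model prediction, and the beam is held whenever the 3D discrepancy
exceeds a user-set tolerance (e.g., 3 mm).

The clinical system's model family is proprietary; here each axis is fit
with the simplest form that captures amplitude nonlinearity and hysteresis:

    pos_axis = a0 + a1*s + a2*s^2 + b1*v

where ``s`` is the surrogate displacement and ``v`` its time derivative
(the velocity term separates inhale from exhale, resolving hysteresis
loops). The fitting interface is pluggable: any design-matrix builder with
the same signature can replace the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reconstruction import MotionTrace3D, PAIR_TIME_TOL

__all__ = [
    "SurrogateState",
    "surrogate_states",
    "CorrelationModel",
    "VerificationRecord",
    "fit_model",
    "predict",
    "model_residuals",
    "verify_tracking",
    "verification_summary",
]

AXES = ("ml", "si", "ap")
BEAM_ON = "ON"
BEAM_HOLD = "HOLD"


@dataclass(frozen=True)
class SurrogateState:
    """External IR surrogate sample: displacement and its velocity."""

    time_s: float
    signal_mm: float
    velocity_mm_s: float


def surrogate_states(times, signal) -> list:
    """Build surrogate states from a sampled signal.

    Velocity is the finite-difference derivative: central differences in
    the interior, one-sided at the endpoints (``numpy.gradient``).
    """
    times = np.asarray(times, dtype=float)
    signal = np.asarray(signal, dtype=float)
    vel = (np.gradient(signal, times) if len(times) > 1
           else np.zeros_like(signal))
    return [
        SurrogateState(float(t), float(s), float(v))
        for t, s, v in zip(times, signal, vel)
    ]


def _design_matrix(s: np.ndarray, v: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(s), s, s * s, v])


@dataclass
class CorrelationModel:
    """Fitted per-axis quadratic + velocity map from surrogate to position.

    ``coeffs`` is (3 axes, 4 terms) ordered (a0, a1, a2, b1). Fit-time
    ranges of signal and velocity are stored so predictions beyond them can
    be flagged as extrapolation.
    """

    coeffs: np.ndarray  # (3, 4)
    signal_range: tuple  # (min, max) mm seen during fitting
    velocity_range: tuple  # (min, max) mm/s
    residual_mean: np.ndarray  # (3,) mean absolute residual per axis, mm
    residual_sd: np.ndarray  # (3,) SD (n-1) of absolute residuals, mm
    n_fit: int = 0
    coeff_se: np.ndarray | None = None  # (3, 4) standard errors

    def is_extrapolating(self, state: SurrogateState, slack: float = 0.10) -> bool:
        """True when signal or velocity exceeds the fit range by > slack
        (fraction of the fitted span)."""
        for val, (lo, hi) in (
            (state.signal_mm, self.signal_range),
            (state.velocity_mm_s, self.velocity_range),
        ):
            span = hi - lo
            margin = slack * span
            if val < lo - margin or val > hi + margin:
                return True
        return False


def _match_states(states, trace: MotionTrace3D):
    st_times = np.array([s.time_s for s in states])
    idx_s, idx_t = [], []
    j = 0
    for i, t in enumerate(trace.times):
        while j < len(st_times) and st_times[j] < t - PAIR_TIME_TOL:
            j += 1
        if j < len(st_times) and abs(st_times[j] - t) <= PAIR_TIME_TOL:
            idx_s.append(j)
            idx_t.append(i)
    return idx_s, idx_t


def fit_model(states, internal: MotionTrace3D) -> CorrelationModel:
    """Least-squares fit of the correlation model on time-matched samples.

    Requires at least 20 matched samples spanning at least two breathing
    cycles' worth of surrogate excursion. Raises on a rank-deficient design
    (e.g., constant surrogate signal).
    """
    idx_s, idx_t = _match_states(states, internal)
    if len(idx_s) < 20:
        raise ValueError(f"only {len(idx_s)} time-matched samples; need >= 20")
    s = np.array([states[j].signal_mm for j in idx_s])
    v = np.array([states[j].velocity_mm_s for j in idx_s])
    y = internal.positions[idx_t]
    X = _design_matrix(s, v)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant surrogate signal?)")
    coeffs, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coeffs
    ar = np.abs(resid)
    n, p = X.shape
    # Per-axis coefficient standard errors from the unbiased residual variance.
    XtX_inv = np.linalg.inv(X.T @ X)
    dof = max(n - p, 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(sigma2, np.diag(XtX_inv)))
    return CorrelationModel(
        coeffs=coeffs.T.copy(),  # (3 axes, 4 terms)
        signal_range=(float(s.min()), float(s.max())),
        velocity_range=(float(v.min()), float(v.max())),
        residual_mean=ar.mean(axis=0),
        residual_sd=ar.std(axis=0, ddof=1) if n > 1 else np.zeros(3),
        n_fit=n,
        coeff_se=se,
    )


def predict(model: CorrelationModel, state: SurrogateState):
    """Predicted internal 3D position (mm) for one surrogate state.

    Returns (position (3,), extrapolating: bool). Defined for any input;
    the flag marks states outside the fitted signal/velocity range by more
    than 10% of the fitted span.
    """
    x = np.array(
        [1.0, state.signal_mm, state.signal_mm**2, state.velocity_mm_s]
    )
    return model.coeffs @ x, model.is_extrapolating(state)


def model_residuals(model: CorrelationModel, states, internal: MotionTrace3D):
    """Per-axis (mean absolute deviation, SD) of detected-minus-model.

    This is the model-building quality statistic: how far the kV-detected
    positions sit from the fitted prediction curve, per axis, mm. SD uses
    the n-1 denominator on the absolute-deviation series.
    """
    idx_s, idx_t = _match_states(states, internal)
    if not idx_s:
        raise ValueError("no time-matched samples")
    pred = np.stack([predict(model, states[j])[0] for j in idx_s])
    ar = np.abs(internal.positions[idx_t] - pred)
    sd = ar.std(axis=0, ddof=1) if len(ar) > 1 else np.zeros(3)
    return ar.mean(axis=0), sd


@dataclass(frozen=True)
class VerificationRecord:
    """One verification-imaging comparison of detected vs predicted position.

    ``beam_status`` is HOLD exactly when the 3D vector difference strictly
    exceeds the tolerance (a difference equal to the tolerance keeps the
    beam on).
    """

    time_s: float
    detected: np.ndarray  # (3,) mm
    predicted: np.ndarray  # (3,) mm
    vector_diff_mm: float
    beam_status: str
    extrapolating: bool = False


def verify_tracking(
    model: CorrelationModel,
    detections: MotionTrace3D,
    states,
    tolerance_mm: float = 3.0,
) -> list:
    """Compare verification detections against model predictions.

    For each verification frame (detections reconstructed at ~1 Hz), the
    3D vector difference ||detected - predicted|| is computed and the beam
    status derived: HOLD iff the difference strictly exceeds
    ``tolerance_mm``.
    """
    idx_s, idx_t = _match_states(states, detections)
    records = []
    for j, i in zip(idx_s, idx_t):
        pred, extrap = predict(model, states[j])
        det = detections.positions[i]
        diff = float(np.linalg.norm(det - pred))
        records.append(
            VerificationRecord(
                time_s=float(detections.times[i]),
                detected=det,
                predicted=pred,
                vector_diff_mm=diff,
                beam_status=BEAM_HOLD if diff > tolerance_mm else BEAM_ON,
                extrapolating=extrap,
            )
        )
    return records


def verification_summary(records) -> dict:
    """Mean absolute 3D deviation, its SD (n-1), and the beam-hold fraction."""
    if not records:
        raise ValueError("no verification records")
    diffs = np.array([r.vector_diff_mm for r in records])
    return {
        "mean_3d_mm": float(diffs.mean()),
        "sd_3d_mm": float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0,
        "hold_fraction": float(np.mean([r.beam_status == BEAM_HOLD for r in records])),
        "n": len(records),
    }
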