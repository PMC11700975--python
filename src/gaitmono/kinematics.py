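"""Spatial gait features from 3D joint coordinates.

The ten spatial parameters are built from four frame-wise signals:

* knee angle  theta_i = arccos((H-K)·(A-K) / (|H-K| |A-K|)),  per side,
* thigh angle — the opening angle between the two thigh vectors K_L-H_L
  and K_R-H_R,
* their first and second finite-difference rates  w_i = f (theta_i -
  theta_{i-1}),  a_i = f (w_i - w_{i-1}),
* step length  L_i = |A_L - A_R|  (full 3D inter-ankle distance, mm).

Ranges of motion are max - min over the segment; "thigh angle max" is the
series maximum.  Angles are in radians, rates in rad/s and rad/s^2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateGeometryError, InsufficientDataError, ParameterError
from .pose_model import PoseSequence

#: Tolerated floating-point overshoot of |cos| beyond 1 before we refuse to clamp.
_COS_SLACK = 1e-6


@dataclass(frozen=True)
class JointTriplet:
    """Hip/knee/ankle coordinates of one leg at one frame."""

    H: np.ndarray
    K: np.ndarray
    A: np.ndarray
    side: str = "L"
    frame: int = 0


@dataclass
class SignalSeries:
    """A named frame-wise signal with its sampling frequency."""

    values: np.ndarray
    fs: float
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def _angle_between(u: np.ndarray, v: np.ndarray, what: str) -> np.ndarray:
    """Angle in [0, pi] between stacked vectors, with clamped arccos."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    bad = (nu == 0) | (nv == 0)
    if np.any(bad):
        frame = int(np.argmax(np.atleast_1d(bad)))
        raise DegenerateGeometryError(
            f"zero-length {what} vector at frame {frame}")
    c = np.sum(u * v, axis=-1) / (nu * nv)
    if np.any(np.abs(c) > 1.0 + _COS_SLACK):
        raise DegenerateGeometryError(f"cosine of {what} angle out of range")
    return np.arccos(np.clip(c, -1.0, 1.0))


def knee_angle(t: JointTriplet) -> float:
    """Knee angle (rad) between thigh vector H-K and shank vector A-K.

    pi is a fully extended leg; flexion reduces the angle.
    """
    return float(_angle_between(np.asarray(t.H) - np.asarray(t.K),
                                np.asarray(t.A) - np.asarray(t.K), "knee"))


def thigh_angle(HL: np.ndarray, KL: np.ndarray,
                HR: np.ndarray, KR: np.ndarray) -> float:
    """Inter-thigh opening angle (rad) between K_L-H_L and K_R-H_R."""
    return float(_angle_between(np.asarray(KL) - np.asarray(HL),
                                np.asarray(KR) - np.asarray(HR), "thigh"))


def knee_angle_series(seq: PoseSequence, side: str) -> SignalSeries:
    """Frame-wise knee angle for one side ('L' or 'R')."""
    if side not in ("L", "R"):
        raise ParameterError(f"side must be 'L' or 'R', got {side!r}")
    H = seq.joint(f"hip_{side}")
    K = seq.joint(f"knee_{side}")
    A = seq.joint(f"ankle_{side}")
    return SignalSeries(_angle_between(H - K, A - K, "knee"),
                        seq.fs, name=f"knee_angle_{side}")


def thigh_angle_series(seq: PoseSequence) -> SignalSeries:
    """Frame-wise inter-thigh opening angle."""
    vals = _angle_between(seq.joint("knee_L") - seq.joint("hip_L"),
                          seq.joint("knee_R") - seq.joint("hip_R"), "thigh")
    return SignalSeries(vals, seq.fs, name="thigh_angle")


def finite_rate(series: SignalSeries) -> SignalSeries:
    """Backward-difference rate:  out_i = fs * (x_{i+1} - x_i).

    Output is one sample shorter; applying it twice yields the
    second-difference acceleration.  Units gain a factor of Hz.
    """
    if len(series) < 2:
        raise InsufficientDataError(
            f"rate of {series.name or 'series'} needs >= 2 samples")
    return SignalSeries(series.fs * np.diff(series.values), series.fs,
                        name=f"d_{series.name}")


def step_length_series(seq: PoseSequence) -> SignalSeries:
    """Per-frame 3D inter-ankle distance, millimetres."""
    d = np.linalg.norm(seq.joint("ankle_L") - seq.joint("ankle_R"), axis=1)
    return SignalSeries(d, seq.fs, name="step_length")


def rom(series: SignalSeries | np.ndarray) -> float:
    """Range of motion: max - min of the series."""
    vals = series.values if isinstance(series, SignalSeries) else np.asarray(series)
    if vals.size == 0:
        raise InsufficientDataError("ROM of an empty series is undefined")
    return float(np.max(vals) - np.min(vals))


def smooth(series: SignalSeries, window: int) -> SignalSeries:
    """Centered moving average with edge reflection (odd window)."""
    if window <= 1:
        return series
    if window % 2 == 0:
        raise ParameterError(f"smoothing window must be odd, got {window}")
    half = window // 2
    padded = np.pad(series.values, half, mode="reflect")
    kernel = np.ones(window) / window
    vals = np.convolve(padded, kernel, mode="valid")
    return replace(series, values=vals)


def spatial_features(seq: PoseSequence,
                     angle_smooth_window: int | None = None) -> dict[str, float]:
    """The 10 spatial gait parameters of a segment.

    No smoothing is applied by default; ``angle_smooth_window`` optionally
    moving-averages the angle series before differentiation.
    """
    out: dict[str, float] = {}
    thigh = thigh_angle_series(seq)
    series = {
        "lknee": knee_angle_series(seq, "L"),
        "rknee": knee_angle_series(seq, "R"),
        "thigh": thigh,
    }
    if angle_smooth_window:
        series = {k: smooth(s, angle_smooth_window) for k, s in series.items()}
    for key, s in series.items():
        vel = finite_rate(s)
        acc = finite_rate(vel)
        if key == "thigh":
            out["thigh_angle_max"] = float(np.max(s.values))
        else:
            out[f"{key}_angle_rom"] = rom(s)
        out[f"{key}_angle_velocity_rom"] = rom(vel)
        out[f"{key}_angle_acc_rom"] = rom(acc)
    out["step_length_max"] = float(np.max(step_length_series(seq).values))
    return out
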