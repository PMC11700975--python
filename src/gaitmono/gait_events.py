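"""Gait event detection, keyframe fusion, and temporal features.

Events follow the video-keyframe conventions:

* heel strike ``F_touch``: local maximum of the inter-ankle-distance
  series — the feet are farthest apart at initial contact;
* toe-off ``F_split``: the frame, between two heel strikes, at which the
  swinging ankle's vertical coordinate peaks — taken as the moment the
  trailing toe leaves the ground.

From the ordered events, per index i (consecutive F_touch are alternating
feet, so i -> i+1 spans one step and i -> i+2 one stride):

    single_step_time_i    = (F_touch_{i+1} - F_touch_i) / fs
    single_support_time_i = (F_split_{i+1} - F_touch_i) / fs
    double_support_time_i = (F_split_i   - F_touch_i) / fs
    stride_time_i         = (F_touch_{i+2} - F_touch_i) / fs
    double_proportion_i   = 100 * double_support_time_i / single_step_time_i
    swing_proportion_i    = 100 - double_proportion_i

and segment values are means over the available indices.  Frame counts
are divided by the sampling frequency to obtain seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import InsufficientDataError
from .kinematics import (SignalSeries, rom, smooth, spatial_features,
                         step_length_series)
from .keyframe_select import select_keyframes
from .pose_model import GaitFeatureSet, PoseSequence


@dataclass
class GaitEventSeries:
    """Ordered heel-strike and toe-off frame indices with side labels."""

    heel_strikes: np.ndarray
    toe_offs: np.ndarray
    fs: float
    heel_strike_sides: list[str] = field(default_factory=list)
    toe_off_sides: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.heel_strikes = np.asarray(self.heel_strikes, dtype=int)
        self.toe_offs = np.asarray(self.toe_offs, dtype=int)


@dataclass
class TemporalFeatureSet:
    """Segment means of the six temporal gait parameters."""

    single_step_time: float
    single_support_time: float
    double_support_time: float
    double_proportion: float
    swing_proportion: float
    stride_time: float

    def as_dict(self) -> dict[str, float]:
        return {
            "single_step_time": self.single_step_time,
            "single_support_time": self.single_support_time,
            "double_support_time": self.double_support_time,
            "double_proportion": self.double_proportion,
            "swing_proportion": self.swing_proportion,
            "stride_time": self.stride_time,
        }


@dataclass
class ExtractionConfig:
    """Tunable knobs of the event-detection / feature pipeline."""

    smooth_window: int = 3          # frames; peak-detection pre-smoothing
    min_separation_s: float = 0.3   # minimum spacing between heel strikes
    prominence_frac: float = 0.2    # of the step-series ROM
    angle_smooth_window: int | None = None
    fusion: bool = False            # filter events against DPC-kNN keyframes
    fusion_tolerance: int = 3       # frames (~100 ms at 30 Hz)
    fusion_m: int | None = None     # keyframe budget; default F // 4
    fusion_k: int | None = None     # kNN size; default ceil(sqrt(F))


def detect_heel_strikes(step_series: SignalSeries,
                        min_separation: int | None = None,
                        smooth_window: int = 3,
                        prominence_frac: float = 0.2) -> np.ndarray:
    """Heel-strike frames: prominent maxima of the inter-ankle distance.

    The series is moving-average smoothed before peak picking; each peak
    is then refined to the local maximum of the raw series within one
    frame, so returned indices refer to the unsmoothed signal.  A series
    with no qualifying peaks yields an empty array with a warning, not an
    exception.
    """
    if len(step_series) < 3:
        raise InsufficientDataError("peak detection needs >= 3 samples")
    if min_separation is None:
        min_separation = max(1, int(round(0.3 * step_series.fs)))
    smoothed = smooth(step_series, smooth_window).values
    span = float(np.max(smoothed) - np.min(smoothed))
    if span == 0.0:
        warnings.warn("inter-ankle distance is constant; no gait events found",
                      stacklevel=2)
        return np.array([], dtype=int)
    peaks, _ = find_peaks(smoothed, distance=min_separation,
                          prominence=prominence_frac * span)
    if len(peaks) == 0:
        warnings.warn("no heel-strike peaks found", stacklevel=2)
        return peaks.astype(int)
    raw = step_series.values
    refined = []
    for p in peaks:
        lo, hi = max(0, p - 1), min(len(raw), p + 2)
        refined.append(lo + int(np.argmax(raw[lo:hi])))
    return np.unique(refined).astype(int)


def detect_toe_offs(seq: PoseSequence, heel_strikes: np.ndarray,
                    ) -> tuple[np.ndarray, list[str]]:
    """Toe-off frames between consecutive heel strikes, with side labels.

    Within each inter-strike interval the swinging side is the ankle with
    the larger vertical excursion; its height maximum marks the toe-off.
    Returns ``(frames, sides)`` where ``sides[i]`` names the foot that
    leaves the ground.
    """
    heel_strikes = np.asarray(heel_strikes, dtype=int)
    if len(heel_strikes) < 2:
        return np.array([], dtype=int), []
    v = seq.vertical_axis
    heights = {side: seq.joint(f"ankle_{side}")[:, v] for side in ("L", "R")}
    frames: list[int] = []
    sides: list[str] = []
    for a, b in zip(heel_strikes[:-1], heel_strikes[1:]):
        interior = np.arange(a + 1, b)
        if len(interior) == 0:
            warnings.warn(f"no interior frames between heel strikes {a} and {b}; "
                          "toe-off omitted", stacklevel=2)
            continue
        excursion = {s: float(np.ptp(h[interior])) for s, h in heights.items()}
        side = max(excursion, key=excursion.get)
        apex = interior[int(np.argmax(heights[side][interior]))]
        frames.append(int(apex))
        sides.append(side)
    return np.asarray(frames, dtype=int), sides


def fuse_keyframes(candidate_events: np.ndarray, reference_keyframes: np.ndarray,
                   tolerance: int) -> np.ndarray:
    """Filter candidate event frames against reference keyframes.

    A candidate survives iff it is the nearest candidate (ties to the
    earlier frame) to some reference keyframe within ``tolerance`` frames.
    This mirrors filtering one pose stream's keyframes by a second,
    independent stream's keyframes.  The operation is idempotent.
    """
    cand = np.asarray(candidate_events, dtype=int)
    ref = np.asarray(reference_keyframes, dtype=int)
    if len(cand) == 0 or len(ref) == 0:
        return np.array([], dtype=int)
    kept: set[int] = set()
    for r in ref:
        d = np.abs(cand - r)
        within = d <= tolerance
        if not within.any():
            continue
        best = np.min(d[within])
        # tie -> earlier frame: candidates are sorted, argmax finds first
        kept.add(int(cand[within][np.argmax(d[within] == best)]))
    return np.array(sorted(kept), dtype=int)


def detect_events(seq: PoseSequence,
                  config: ExtractionConfig | None = None) -> GaitEventSeries:
    """Full multi-level event detection for one segment."""
    cfg = config or ExtractionConfig()
    series = step_length_series(seq)
    hs = detect_heel_strikes(
        series,
        min_separation=max(1, int(round(cfg.min_separation_s * seq.fs))),
        smooth_window=cfg.smooth_window,
        prominence_frac=cfg.prominence_frac,
    )
    if cfg.fusion and len(hs):
        m = cfg.fusion_m if cfg.fusion_m is not None else max(4, seq.n_frames // 4)
        reference = select_keyframes(seq, m=m, k=cfg.fusion_k)
        hs = fuse_keyframes(hs, reference, cfg.fusion_tolerance)
    to, to_sides = detect_toe_offs(seq, hs)
    # a heel strike is on the opposite foot of the one swinging just after it
    hs_sides: list[str] = []
    flip = {"L": "R", "R": "L"}
    for i in range(len(hs)):
        if i < len(to_sides):
            hs_sides.append(flip[to_sides[i]])
        elif hs_sides:
            hs_sides.append(flip[hs_sides[-1]])
        else:
            hs_sides.append("L")
    return GaitEventSeries(hs, to, seq.fs, hs_sides, to_sides)


def temporal_features(events: GaitEventSeries) -> TemporalFeatureSet:
    """Segment means of the six temporal parameters from ordered events."""
    hs = events.heel_strikes
    to = events.toe_offs
    fs = events.fs
    if len(hs) < 3:
        raise InsufficientDataError(
            f"temporal features need >= 3 heel strikes, got {len(hs)}")
    if len(to) < 2:
        raise InsufficientDataError(
            f"temporal features need >= 2 toe-offs, got {len(to)}")
    steps = np.diff(hs) / fs
    strides = (hs[2:] - hs[:-2]) / fs
    n_d = min(len(to), len(hs))
    doubles = (to[:n_d] - hs[:n_d]) / fs
    n_s = min(len(to) - 1, len(hs))
    singles = (to[1:n_s + 1] - hs[:n_s]) / fs
    n_p = min(len(doubles), len(steps))
    proportions = 100.0 * doubles[:n_p] / steps[:n_p]
    return TemporalFeatureSet(
        single_step_time=float(np.mean(steps)),
        single_support_time=float(np.mean(singles)),
        double_support_time=float(np.mean(doubles)),
        double_proportion=float(np.mean(proportions)),
        swing_proportion=float(np.mean(100.0 - proportions)),
        stride_time=float(np.mean(strides)),
    )


def extract_all(seq: PoseSequence,
                config: ExtractionConfig | None = None) -> GaitFeatureSet:
    """All 16 gait parameters (6 temporal + 10 spatial) for one segment."""
    cfg = config or ExtractionConfig()
    features = spatial_features(seq, angle_smooth_window=cfg.angle_smooth_window)
    events = detect_events(seq, cfg)
    temporal = temporal_features(events)
    features.update(temporal.as_dict())
    return GaitFeatureSet(features=features, subject_id=seq.subject_id,
                          segment_id=seq.segment_id)
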