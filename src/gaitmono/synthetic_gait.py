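"""Synthetic 3D lower-limb walking sequences with known ground truth.

The generator stands in for the neural pose estimators and the clinical
cohort: it emits pose sequences in the same ``(F, J, 3)`` millimetre
format a video pipeline would, together with the exact gait events and
parameter values that produced them, so every downstream stage can be
tested for parameter recovery.

Kinematic model (sagittal-dominant, per leg, stride phase u in [0, 1)):

* the pelvis translates forward at the mean speed step_length/step_time;
  hips sit a fixed pelvis_width apart and "vault" vertically at the
  step period, as in compass gait;
* each ankle sweeps fore-aft as a pure cosine relative to the pelvis,
  sized so the maximum 3D inter-ankle distance equals step_length
  exactly at the heel-strike instants;
* an asymmetric raised-cosine swing lift raises the ankle between the
  contralateral strike and terminal swing, peaking exactly at the
  toe-off instant — the keyframe convention by which toe-off is
  detected downstream; its height is solved so the knee-angle range of
  motion equals knee_rom;
* the knee follows from planar two-segment inverse kinematics, with a
  pelvis vertical "vault" that keeps the stance leg near constant
  extension.

Heel strikes fall where the inter-ankle distance peaks (exactly
step_time apart, by the half-stride symmetry of antiphase legs); the
toe-off of the trailing foot follows the contralateral heel strike by
double_support_fraction * step_time.  Gaussian coordinate noise emulates
pose-estimator error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigurationError, ParameterError
from .kinematics import SignalSeries, finite_rate, rom
from .pose_model import (GROUPS, GaitFeatureSet, PoseSequence,
                         REQUIRED_JOINTS, features_to_table)

# shape constants (stride-phase units unless noted)
_BASE_EXTENSION = 0.99         # hip-ankle distance at strike, of leg_length
_PAD_STEPS = 0.6               # lead-in/out, in units of step_time


class _StepTooShort(ConfigurationError):
    """Swing-phase inter-ankle distance exceeds the requested step length."""


@dataclass
class GaitParams:
    """Generator parameters for one walking segment.

    Defaults are the healthy-elderly preset; magnitudes follow published
    gold-standard means (step time 0.54 s, step length 553 mm, knee ROM
    0.91 rad).  ``thigh_angle_max`` is derived — in a linked two-segment
    model the inter-thigh opening angle follows from step length, leg
    length and pelvis width — and is recorded in the ground truth.
    """

    step_time: float = 0.54                # s, between alternating heel strikes
    step_length: float = 553.0             # mm, max inter-ankle distance
    double_support_fraction: float = 0.222  # of step_time, in (0, 0.5)
    knee_rom: float = 0.91                 # rad, knee-angle range of motion
    thigh_angle_max: float | None = None   # rad; derived when None
    n_cycles: int = 2                      # gait cycles (strides) per segment
    fs: float = 30.0                       # Hz
    noise_sd: float = 3.0                  # mm, per-coordinate Gaussian noise
    seed: int = 0
    leg_length: float = 800.0              # mm, hip to ankle (thigh = shank)
    pelvis_width: float = 200.0            # mm, hip-to-hip

    def validate(self) -> "GaitParams":
        positive = ("step_time", "step_length", "knee_rom", "fs",
                    "leg_length", "pelvis_width")
        for name in positive:
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if not 0 < self.double_support_fraction < 0.5:
            raise ParameterError("double_support_fraction must lie in (0, 0.5)")
        if self.n_cycles < 2:
            raise ConfigurationError(
                "a segment must cover at least 2 gait cycles")
        if self.step_length <= self.pelvis_width:
            raise ParameterError("step_length must exceed pelvis_width")
        if math.hypot(self.step_length, 0) >= 2 * self.leg_length:
            raise ParameterError("step_length is unreachable for this leg length")
        return self


@dataclass
class SyntheticGroundTruth:
    """Exact events and parameter values behind a generated sequence."""

    true_heel_strikes: np.ndarray          # frame indices
    heel_strike_sides: list[str]
    true_toe_offs: np.ndarray              # frame indices
    toe_off_sides: list[str]
    heel_strike_times: np.ndarray          # seconds (analytic)
    toe_off_times: np.ndarray
    true_features: GaitFeatureSet
    params: GaitParams


def _bump_asym(u: np.ndarray, center: float, rise: float,
               fall: float) -> np.ndarray:
    """Asymmetric raised-cosine bump of unit height on the circular phase.

    Rises over ``rise`` phase units, peaks exactly at ``center``, falls
    over ``fall`` units; zero elsewhere.
    """
    w = u - center
    w = w - np.round(w)  # wrap to [-0.5, 0.5)
    out = np.zeros_like(w, dtype=float)
    up = (w > -rise) & (w <= 0)
    down = (w > 0) & (w < fall)
    out[up] = 0.5 * (1.0 + np.cos(np.pi * w[up] / rise))
    out[down] = 0.5 * (1.0 + np.cos(np.pi * w[down] / fall))
    return out


class _GaitModel:
    """Continuous noiseless kinematics for one segment's parameters.

    The stride phase u runs in [0, 1) per leg, u = 0 at that leg's own
    heel strike; the right leg trails the left by half a stride.  The
    ankle paths are designed directly so every event convention holds in
    closed form, and the knee is recovered by two-segment inverse
    kinematics, keeping the hip-knee-ankle chain geometrically exact:

    * ankle fore-aft position (pelvis frame): x(u) = R cos(2 pi u) with
      R = sqrt(step_length^2 - pelvis_width^2) / 2, so the 3D
      inter-ankle distance peaks at exactly step_length at u = 0;
    * ankle height: an asymmetric raised-cosine swing lift whose peak
      sits exactly at the toe-off instant (one double-support interval
      after the contralateral strike) and whose support excludes the
      strikes, so it never perturbs the separation peak;
    * pelvis height "vaults" at the step period with amplitude chosen so
      the stance-phase hip-ankle distance is constant to fourth order —
      the stance knee stays near its strike flexion;
    * the lift height is solved so the knee-angle range of motion
      equals knee_rom.
    """

    def __init__(self, p: GaitParams):
        self.p = p
        self.T = 2.0 * p.step_time                      # stride period, s
        self.u_toe_off = 0.5 + p.double_support_fraction / 2.0
        self.L1 = self.L2 = p.leg_length / 2.0
        self.speed = p.step_length / p.step_time        # mm/s forward
        self.R = 0.5 * math.sqrt(p.step_length ** 2 - p.pelvis_width ** 2)
        # near-full extension at heel strike, with a little slack so the
        # inverse kinematics never locks out
        self.L_base = _BASE_EXTENSION * p.leg_length
        if self.R >= self.L_base:
            raise ConfigurationError("step_length unreachable for this leg length")
        # pelvis vault: with psi = asin((R/L_base)^2)/2, M = L_base cos(psi)
        # and h_a = L_base sin(psi)/2, the stance leg length satisfies
        # L(u)^2 = L_base^2 - 4 h_a^2 (1 - cos(2 pi u)^4): equal at strike
        # and mid-stance, varying only at fourth order in between.
        psi = 0.5 * math.asin((self.R / self.L_base) ** 2)
        self.M = self.L_base * math.cos(psi)            # mid-stance hip height
        self.h_a = 0.5 * self.L_base * math.sin(psi)    # vault amplitude
        self.D_bar = self.M - self.h_a
        # swing-lift bump: rises from zero strictly after the
        # contralateral strike, peaks at toe-off, falls through swing
        dsf = p.double_support_fraction
        self.lift_rise = min(0.12, 0.45 * dsf)
        self.lift_fall = 0.18
        self.lift_height = self._solve_lift_height()
        self._check_dominance()
        self.first_strike_side = "L"

    # -- per-leg profiles over stride phase ----------------------------
    def hip_height(self, u: np.ndarray) -> np.ndarray:
        """Pelvis height above the stance-foot plane (vault at step period)."""
        return self.D_bar - self.h_a * np.cos(4.0 * np.pi * np.asarray(u))

    def ankle_x(self, u: np.ndarray) -> np.ndarray:
        return self.R * np.cos(2.0 * np.pi * np.asarray(u))

    def ankle_z(self, u: np.ndarray) -> np.ndarray:
        return self.lift_height * _bump_asym(
            np.asarray(u), self.u_toe_off, self.lift_rise, self.lift_fall)

    def leg_length_series(self, u: np.ndarray) -> np.ndarray:
        """Hip-to-ankle distance (the IK chain length) per phase."""
        dx = self.ankle_x(u)
        dz = self.hip_height(u) - self.ankle_z(u)
        return np.sqrt(dx ** 2 + dz ** 2)

    def knee_angle(self, u: np.ndarray) -> np.ndarray:
        """Knee angle by the law of cosines; pi = fully extended."""
        L = self.leg_length_series(u)
        c = (self.L1 ** 2 + self.L2 ** 2 - L ** 2) / (2.0 * self.L1 * self.L2)
        return np.arccos(np.clip(c, -1.0, 1.0))

    def _separation(self, u: np.ndarray) -> np.ndarray:
        """3D inter-ankle distance with the left leg at phase u."""
        u = np.asarray(u)
        dx = self.ankle_x(u) - self.ankle_x(u - 0.5)
        dz = self.ankle_z(u) - self.ankle_z(u - 0.5)
        return np.sqrt(dx ** 2 + dz ** 2 + self.p.pelvis_width ** 2)

    def _solve_lift_height(self) -> float:
        """Solve the swing-lift height for the requested knee-angle ROM."""
        grid = np.linspace(0.0, 1.0, 2001)
        target = self.p.knee_rom
        cap = 0.85 * (self.D_bar - self.h_a)

        def gap(h: float) -> float:
            self.lift_height = h
            theta = self.knee_angle(grid)
            return float(np.max(theta) - np.min(theta)) - target

        try:
            if gap(0.0) > 0:
                raise ConfigurationError(
                    "knee_rom below the stance-phase flexion range of this "
                    "step geometry")
            if gap(cap) < 0:
                raise ConfigurationError(
                    "knee_rom unreachable: requested flexion exceeds the "
                    "swing-lift headroom")
            return float(brentq(gap, 0.0, cap, xtol=1e-9))
        finally:
            self.lift_height = 0.0

    def _check_dominance(self) -> None:
        """The heel-strike separation peak must dominate swing structure.

        A short step with a tall swing lift can make the mid-swing 3D
        inter-ankle distance rival the strike peak, which would make
        maximum-distance heel-strike keyframes ambiguous.
        """
        grid = np.linspace(0.0, 1.0, 1001)
        d = self._separation(grid)
        off_peak = np.abs((grid + 0.25) % 0.5 - 0.25) > 0.10
        if d[off_peak].max() > 0.90 * self.p.step_length:
            raise _StepTooShort(
                "swing-phase inter-ankle distance rivals the heel-strike peak")

    # -- timeline -------------------------------------------------------
    @property
    def pad(self) -> float:
        return _PAD_STEPS * self.p.step_time

    @property
    def duration(self) -> float:
        return 2 * self.pad + 2 * self.p.n_cycles * self.p.step_time

    @property
    def t0(self) -> float:
        """Time at which the left leg is at stride phase zero (its strike)."""
        return self.pad

    def heel_strike_times(self) -> np.ndarray:
        k = np.arange(2 * self.p.n_cycles + 1)
        return self.pad + k * self.p.step_time

    def toe_off_times(self) -> np.ndarray:
        strikes = self.heel_strike_times()
        return strikes[:-1] + self.p.double_support_fraction * self.p.step_time

    def phases(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        u_left = (np.asarray(t) - self.t0) / self.T
        return u_left, u_left - 0.5

    def _knee_position(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Sagittal knee position from two-segment inverse kinematics.

        The knee sits posterior to the hip-ankle line (flexion folds the
        chain backward).
        """
        u = np.asarray(u, dtype=float)
        hz = self.hip_height(u)
        ex = self.ankle_x(u)
        ez = self.ankle_z(u) - hz
        L = np.sqrt(ex ** 2 + ez ** 2)
        ex, ez = ex / L, ez / L
        half = L / 2.0  # equal segments: the knee projects onto the midpoint
        h_k = np.sqrt(np.maximum(self.L1 ** 2 - half ** 2, 0.0))
        # perpendicular pointing backward (negative x for a downward e)
        px, pz = ez, -ex
        return ex * half + px * h_k, hz + ez * half + pz * h_k

    def joint_coordinates(self, t: np.ndarray) -> np.ndarray:
        """Noiseless lab-frame coordinates, shape (len(t), 6, 3)."""
        t = np.asarray(t, dtype=float)
        u_l, u_r = self.phases(t)
        w = self.p.pelvis_width / 2.0
        x_pelvis = self.speed * t
        coords = np.empty((len(t), 6, 3))
        idx = {name: i for i, name in enumerate(REQUIRED_JOINTS)}
        for side, u, y in (("L", u_l, +w), ("R", u_r, -w)):
            kx, kz = self._knee_position(u)
            coords[:, idx[f"hip_{side}"], 0] = x_pelvis
            coords[:, idx[f"hip_{side}"], 1] = y
            coords[:, idx[f"hip_{side}"], 2] = self.hip_height(u)
            coords[:, idx[f"knee_{side}"], 0] = x_pelvis + kx
            coords[:, idx[f"knee_{side}"], 1] = y
            coords[:, idx[f"knee_{side}"], 2] = kz
            coords[:, idx[f"ankle_{side}"], 0] = x_pelvis + self.ankle_x(u)
            coords[:, idx[f"ankle_{side}"], 1] = y
            coords[:, idx[f"ankle_{side}"], 2] = self.ankle_z(u)
        return coords

    def thigh_angle(self, u_left: np.ndarray) -> np.ndarray:
        """Inter-thigh opening angle at left-leg phase u_left."""
        vecs = []
        for u in (np.asarray(u_left), np.asarray(u_left) - 0.5):
            kx, kz = self._knee_position(u)
            vecs.append((kx, kz - self.hip_height(u)))
        (lx, lz), (rx, rz) = vecs
        c = (lx * rx + lz * rz) / (np.hypot(lx, lz) * np.hypot(rx, rz))
        return np.arccos(np.clip(c, -1.0, 1.0))

    # -- analytic feature values ----------------------------------------
    def true_features(self, frame_times: np.ndarray) -> dict[str, float]:
        p = self.p
        dsf = p.double_support_fraction
        dense = np.linspace(0.0, 1.0, 4001)
        out = {
            "single_step_time": p.step_time,
            "single_support_time": (1.0 + dsf) * p.step_time,
            "double_support_time": dsf * p.step_time,
            "double_proportion": 100.0 * dsf,
            "swing_proportion": 100.0 * (1.0 - dsf),
            "stride_time": 2.0 * p.step_time,
            "lknee_angle_rom": p.knee_rom,
            "rknee_angle_rom": p.knee_rom,
            "thigh_angle_max": float(np.max(self.thigh_angle(dense))),
            "step_length_max": p.step_length,
        }
        # rate features are defined by the finite-difference operators at
        # the camera rate, applied to the exact noiseless angle samples
        u_l, u_r = self.phases(frame_times)
        knee_l = SignalSeries(self.knee_angle(u_l), p.fs)
        knee_r = SignalSeries(self.knee_angle(u_r), p.fs)
        thigh = SignalSeries(self.thigh_angle(u_l), p.fs)
        for prefix, s in (("lknee", knee_l), ("rknee", knee_r), ("thigh", thigh)):
            vel = finite_rate(s)
            acc = finite_rate(vel)
            out[f"{prefix}_angle_velocity_rom"] = rom(vel)
            out[f"{prefix}_angle_acc_rom"] = rom(acc)
        return out


def generate_gait(params: GaitParams) -> tuple[PoseSequence, SyntheticGroundTruth]:
    """Generate one walking segment plus its exact ground truth.

    Deterministic given ``params.seed``; with ``noise_sd = 0`` the output
    is the exact kinematic model sampled at the camera rate.
    """
    p = params.validate()
    model = _GaitModel(p)
    n_frames = int(math.floor(model.duration * p.fs)) + 1
    t = np.arange(n_frames) / p.fs
    coords = model.joint_coordinates(t)
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        coords = coords + rng.normal(0.0, p.noise_sd, size=coords.shape)
    seq = PoseSequence(coords=coords, fs=p.fs,
                       joint_map={n: i for i, n in enumerate(REQUIRED_JOINTS)},
                       vertical_axis=2).validate()

    hs_times = model.heel_strike_times()
    to_times = model.toe_off_times()
    flip = {"L": "R", "R": "L"}
    hs_sides = [model.first_strike_side if k % 2 == 0
                else flip[model.first_strike_side]
                for k in range(len(hs_times))]
    to_sides = [flip[s] for s in hs_sides[:-1]]  # trailing foot lifts off
    truth = SyntheticGroundTruth(
        true_heel_strikes=np.rint(hs_times * p.fs).astype(int),
        heel_strike_sides=hs_sides,
        true_toe_offs=np.rint(to_times * p.fs).astype(int),
        toe_off_sides=to_sides,
        heel_strike_times=hs_times,
        toe_off_times=to_times,
        true_features=GaitFeatureSet(model.true_features(t)),
        params=p,
    )
    return seq, truth


# ---------------------------------------------------------------------------
# Cohort presets and generation
# ---------------------------------------------------------------------------

#: Preset means: healthy and PD magnitudes from gold-standard tables; the
#: mid-stage preset further scales step length (-15 %) and double-support
#: fraction (+30 %) as a documented modelling choice.
_PRESET_MEANS: dict[str, dict[str, float]] = {
    "healthy": {"step_time": 0.54, "step_length": 553.0,
                "double_support_fraction": 0.222, "knee_rom": 0.91},
    "early_pd": {"step_time": 0.56, "step_length": 491.0,
                 "double_support_fraction": 0.268, "knee_rom": 0.82},
    "mid_pd": {"step_time": 0.56, "step_length": 417.0,
               "double_support_fraction": 0.348, "knee_rom": 0.82},
}

#: Between-subject standard deviations (gold-standard SD columns).
PRESET_BETWEEN_SD: dict[str, dict[str, float]] = {
    "healthy": {"step_time": 0.08, "step_length": 50.0,
                "double_support_fraction": 0.074, "knee_rom": 0.11},
    "early_pd": {"step_time": 0.06, "step_length": 102.0,
                 "double_support_fraction": 0.071, "knee_rom": 0.15},
    "mid_pd": {"step_time": 0.06, "step_length": 102.0,
               "double_support_fraction": 0.071, "knee_rom": 0.15},
}

#: Physical truncation bounds for subject-level draws.
_PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "step_time": (0.40, 1.10),
    "step_length": (380.0, 900.0),
    "double_support_fraction": (0.06, 0.45),
    "knee_rom": (0.30, 1.40),
}

_VARIED_FIELDS = tuple(_PARAM_BOUNDS)


def cohort_preset(name: str) -> GaitParams:
    """Generator parameters for one cohort (healthy, early_pd, mid_pd)."""
    if name not in _PRESET_MEANS:
        raise ParameterError(
            f"unknown preset {name!r}; valid presets: {', '.join(_PRESET_MEANS)}")
    return GaitParams(**_PRESET_MEANS[name]).validate()


def blend_params(base: GaitParams, target: GaitParams, scale: float) -> GaitParams:
    """Linear interpolation of the varied gait parameters (0 = base)."""
    updates = {f: (1 - scale) * getattr(base, f) + scale * getattr(target, f)
               for f in _VARIED_FIELDS}
    return replace(base, **updates)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(200):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def generate_cohort(n_per_group: int | tuple[int, ...],
                    segments_per_subject: int = 3,
                    seed: int = 0,
                    presets: dict[str, GaitParams] | None = None,
                    within_between_ratio: float = 0.25,
                    noise_sd: float | None = None,
                    ) -> tuple[list[PoseSequence], pd.DataFrame]:
    """Generate a multi-subject cohort and its true-feature table.

    Subject-level gait parameters are drawn around each cohort preset with
    the between-subject SDs; each subject's segments vary with a smaller
    within-subject SD (``within_between_ratio`` times the between-subject
    SD, default 1:4), so test-retest reliability on the true features is
    high by construction.
    """
    if isinstance(n_per_group, int):
        counts = {g: n_per_group for g in GROUPS}
    else:
        if len(n_per_group) != len(GROUPS):
            raise ParameterError(
                f"n_per_group needs {len(GROUPS)} entries (one per group)")
        counts = dict(zip(GROUPS, n_per_group))
    if any(c < 0 for c in counts.values()) or sum(counts.values()) < 1:
        raise ParameterError("subject counts must be non-negative, total >= 1")
    if segments_per_subject < 1:
        raise ParameterError("segments_per_subject must be >= 1")
    presets = presets or {g: cohort_preset(g) for g in GROUPS}

    rng = np.random.default_rng(seed)
    sequences: list[PoseSequence] = []
    rows: list[GaitFeatureSet] = []
    for g_idx, group in enumerate(GROUPS):
        preset = presets[group]
        sds = PRESET_BETWEEN_SD[group]
        for s_idx in range(counts[group]):
            subject_id = f"{group[0]}{s_idx:03d}"
            subject_mean = {
                f: _truncated_normal(rng, getattr(preset, f), sds[f],
                                     *_PARAM_BOUNDS[f])
                for f in _VARIED_FIELDS}
            for seg in range(segments_per_subject):
                seg_vals = {
                    f: _truncated_normal(rng, subject_mean[f],
                                         within_between_ratio * sds[f],
                                         *_PARAM_BOUNDS[f])
                    for f in _VARIED_FIELDS}
                params = replace(
                    preset, **seg_vals,
                    seed=int(rng.integers(0, 2 ** 31)),
                    noise_sd=preset.noise_sd if noise_sd is None else noise_sd)
                # rare draws land outside the kinematically feasible region
                # (short step + large knee ROM); nudge them back in
                for _ in range(8):
                    try:
                        seq, truth = generate_gait(params)
                        break
                    except ConfigurationError:
                        params = replace(
                            params,
                            knee_rom=max(0.95 * params.knee_rom,
                                         _PARAM_BOUNDS["knee_rom"][0]),
                            step_length=min(1.05 * params.step_length,
                                            _PARAM_BOUNDS["step_length"][1]))
                else:
                    seq, truth = generate_gait(replace(
                        preset, seed=params.seed, noise_sd=params.noise_sd))
                seq = replace(seq, subject_id=subject_id, segment_id=f"seg{seg}")
                truth.true_features.subject_id = subject_id
                truth.true_features.segment_id = f"seg{seg}"
                truth.true_features.group = group
                sequences.append(seq)
                rows.append(truth.true_features)
    return sequences, features_to_table(rows)


def second_stream(seq: PoseSequence, jitter_sd: float = 0.0,
                  keyframe_shift: int = 0, seed: int | None = None) -> PoseSequence:
    """A perturbed copy of a sequence, as a second pose estimator would see it.

    ``jitter_sd`` adds independent Gaussian coordinate noise;
    ``keyframe_shift`` delays the whole motion by an integer number of
    frames (edge frames repeated), systematically shifting every detected
    gait event by the same amount.
    """
    idx = np.clip(np.arange(seq.n_frames) - keyframe_shift, 0, seq.n_frames - 1)
    coords = seq.coords[idx]
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, jitter_sd, size=coords.shape)
    return replace(seq, coords=coords)
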