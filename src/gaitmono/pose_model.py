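"""Core data types, file I/O, skeleton validation and resampling.

A pose sequence is an ``(F, J, 3)`` array of 3D joint coordinates in
millimetres sampled at a fixed camera rate (30 Hz by default, the rate of
a consumer monocular camera).  Downstream gait analysis needs at least the
six lower-limb joints (left/right hip, knee, ankle); additional joints are
carried along untouched.

Two on-disk formats are supported:

* long-form CSV with header ``frame,joint,x,y,z`` (no metadata; the
  sampling frequency defaults to 30 Hz),
* JSON carrying the coordinate array plus authoritative metadata
  (``fs``, ``vertical_axis``, ``joint_names``, subject/segment labels).

Feature tables are plain :class:`pandas.DataFrame` objects with one row
per walking segment: ``subject_id, segment_id, group`` plus the 16 gait
parameters in :data:`FEATURE_NAMES`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError, ParseError, SkeletonError

#: Joints every sequence must provide (left/right hip, knee, ankle).
REQUIRED_JOINTS: tuple[str, ...] = (
    "hip_L", "hip_R", "knee_L", "knee_R", "ankle_L", "ankle_R",
)

#: The 16 gait parameters, snake_case, temporal first then spatial.
FEATURE_NAMES: tuple[str, ...] = (
    "single_step_time",
    "single_support_time",
    "double_support_time",
    "double_proportion",
    "swing_proportion",
    "stride_time",
    "lknee_angle_rom",
    "rknee_angle_rom",
    "lknee_angle_velocity_rom",
    "rknee_angle_velocity_rom",
    "rknee_angle_acc_rom",
    "lknee_angle_acc_rom",
    "thigh_angle_max",
    "thigh_angle_velocity_rom",
    "thigh_angle_acc_rom",
    "step_length_max",
)

TEMPORAL_FEATURES: tuple[str, ...] = FEATURE_NAMES[:6]
SPATIAL_FEATURES: tuple[str, ...] = FEATURE_NAMES[6:]

#: Cohort labels: healthy elderly, early-stage and mid-stage Parkinson's.
GROUPS: tuple[str, ...] = ("healthy", "early_pd", "mid_pd")

DEFAULT_FS = 30.0
DEFAULT_VERTICAL_AXIS = 2  # z-up unless file metadata says otherwise


@dataclass
class PoseSequence:
    """A 3D pose time series for one walking segment.

    Attributes
    ----------
    coords
        Array of shape ``(F, J, 3)``, millimetres.
    fs
        Sampling frequency in Hz.
    joint_map
        Joint name -> column index; must contain :data:`REQUIRED_JOINTS`.
    vertical_axis
        Which of the three coordinate axes points up (0, 1 or 2).
    """

    coords: np.ndarray
    fs: float = DEFAULT_FS
    joint_map: dict[str, int] = field(default_factory=dict)
    vertical_axis: int = DEFAULT_VERTICAL_AXIS
    subject_id: str | None = None
    segment_id: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.joint_map and self.coords.ndim == 3 and self.coords.shape[1] == 6:
            self.joint_map = {name: i for i, name in enumerate(REQUIRED_JOINTS)}

    # -- basic geometry ------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_joints(self) -> int:
        return int(self.coords.shape[1])

    @property
    def duration(self) -> float:
        """Time spanned by the sequence, ``(F - 1) / fs`` seconds."""
        return (self.n_frames - 1) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fs

    def joint(self, name: str) -> np.ndarray:
        """Return the ``(F, 3)`` trajectory of a named joint."""
        try:
            return self.coords[:, self.joint_map[name], :]
        except KeyError:
            raise SkeletonError(f"joint {name!r} not present in joint_map") from None

    def validate(self) -> "PoseSequence":
        """Check the sequence invariants, raising on violation."""
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ParseError(f"coords must have shape (F, J, 3), got {self.coords.shape}")
        if self.n_frames < 2:
            raise InsufficientDataError("a pose sequence needs at least 2 frames")
        if not self.fs > 0:
            raise ParameterError(f"sampling frequency must be positive, got {self.fs}")
        if self.vertical_axis not in (0, 1, 2):
            raise ParameterError(f"vertical_axis must be 0, 1 or 2, got {self.vertical_axis}")
        missing = [j for j in REQUIRED_JOINTS if j not in self.joint_map]
        if missing:
            raise SkeletonError(f"missing required joints: {', '.join(missing)}")
        if max(self.joint_map.values()) >= self.n_joints:
            raise ParseError("joint_map indexes beyond coordinate array")
        if not np.isfinite(self.coords).all():
            raise ParseError("non-finite coordinates present; run validate_skeleton "
                             "to locate and drop the offending frames")
        return self


@dataclass(frozen=True)
class SkeletonIssue:
    """A quality-control finding for one frame/joint."""

    frame: int
    joint: str
    reason: str  # "non_finite" or "all_zero"

    def __str__(self) -> str:
        return f"frame {self.frame}: joint {self.joint} is {self.reason}"


def validate_skeleton(seq: PoseSequence) -> list[SkeletonIssue]:
    """Report frames whose required joints are non-finite or all-zero.

    An empty list means the sequence is usable as-is.  Mirrors the video
    quality control step of dropping frames with incomplete subject
    visibility: a pose estimator typically emits zeros or NaNs there.
    """
    issues: list[SkeletonIssue] = []
    for name in REQUIRED_JOINTS:
        if name not in seq.joint_map:
            continue
        xyz = seq.coords[:, seq.joint_map[name], :]
        bad = ~np.isfinite(xyz).all(axis=1)
        zero = np.all(xyz == 0.0, axis=1)
        for f in np.nonzero(bad)[0]:
            issues.append(SkeletonIssue(int(f), name, "non_finite"))
        for f in np.nonzero(zero & ~bad)[0]:
            issues.append(SkeletonIssue(int(f), name, "all_zero"))
    issues.sort(key=lambda i: (i.frame, i.joint))
    return issues


def drop_bad_frames(seq: PoseSequence) -> PoseSequence:
    """Return a copy with all frames flagged by :func:`validate_skeleton` removed."""
    bad = {i.frame for i in validate_skeleton(seq)}
    if not bad:
        return seq
    keep = np.array([f for f in range(seq.n_frames) if f not in bad])
    return replace(seq, coords=seq.coords[keep])


# ---------------------------------------------------------------------------
# Pose sequence I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise ParameterError(f"cannot infer pose file format from {path.name!r}; "
                         "pass format='csv' or 'json'")


def read_pose_sequence(path: str | Path, format: str | None = None,
                       fs: float = DEFAULT_FS,
                       vertical_axis: int = DEFAULT_VERTICAL_AXIS) -> PoseSequence:
    """Read a pose sequence from long-form CSV or JSON.

    CSV carries no metadata, so ``fs`` and ``vertical_axis`` provide the
    defaults; JSON metadata is authoritative and overrides them.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    if fmt == "json":
        return _read_pose_json(path)
    if fmt == "csv":
        return _read_pose_csv(path, fs=fs, vertical_axis=vertical_axis)
    raise ParameterError(f"unknown pose format {fmt!r} (expected 'csv' or 'json')")


def _read_pose_json(path: Path) -> PoseSequence:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path.name}: invalid JSON ({exc})") from exc
    try:
        joint_names = list(payload["joint_names"])
        coords = np.asarray(payload["coords"], dtype=float)
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path.name}: JSON must carry 'joint_names' and a "
                         f"rectangular 'coords' array ({exc})") from exc
    seq = PoseSequence(
        coords=coords,
        fs=float(payload.get("fs", DEFAULT_FS)),
        joint_map={name: i for i, name in enumerate(joint_names)},
        vertical_axis=int(payload.get("vertical_axis", DEFAULT_VERTICAL_AXIS)),
        subject_id=payload.get("subject_id"),
        segment_id=payload.get("segment_id"),
    )
    return seq.validate()


def _read_pose_csv(path: Path, fs: float, vertical_axis: int) -> PoseSequence:
    header_cols = ("frame", "joint", "x", "y", "z")
    try:
        df = pd.read_csv(path, dtype={"joint": str})
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise ParseError(f"{path.name}: malformed CSV ({exc})") from exc
    if list(df.columns) != list(header_cols):
        raise ParseError(f"{path.name}: expected header {','.join(header_cols)}, "
                         f"got {','.join(map(str, df.columns))}")
    for col in ("frame", "x", "y", "z"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            # +2: 1-based line numbers plus the header line
            line = int(bad.idxmax()) + 2
            raise ParseError(f"{path.name}: non-numeric value in column "
                             f"{col!r} at line {line}")
    df["frame"] = df["frame"].astype(int)
    joints = list(dict.fromkeys(df["joint"]))  # order of first appearance
    missing = [j for j in REQUIRED_JOINTS if j not in joints]
    if missing:
        raise SkeletonError(f"{path.name}: missing required joints: "
                            f"{', '.join(missing)}")
    frames = np.sort(df["frame"].unique())
    wide = df.set_index(["frame", "joint"])
    if wide.index.has_duplicates:
        raise ParseError(f"{path.name}: duplicated (frame, joint) rows")
    coords = np.full((len(frames), len(joints), 3), np.nan)
    frame_pos = {f: i for i, f in enumerate(frames)}
    joint_pos = {j: i for i, j in enumerate(joints)}
    coords[df["frame"].map(frame_pos), df["joint"].map(joint_pos), :] = (
        df[["x", "y", "z"]].to_numpy(dtype=float)
    )
    if np.isnan(coords).any():
        holes = np.argwhere(np.isnan(coords[:, :, 0]))
        f, j = holes[0]
        raise ParseError(f"{path.name}: incomplete frame grid — e.g. joint "
                         f"{joints[j]!r} has no row for frame {frames[f]}")
    seq = PoseSequence(coords=coords, fs=fs,
                       joint_map=joint_pos, vertical_axis=vertical_axis)
    return seq.validate()


def write_pose_sequence(seq: PoseSequence, path: str | Path,
                        format: str | None = None) -> Path:
    """Write a pose sequence to CSV or JSON (format inferred from suffix)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    names = sorted(seq.joint_map, key=seq.joint_map.get)
    if fmt == "json":
        payload = {
            "fs": seq.fs,
            "vertical_axis": seq.vertical_axis,
            "joint_names": names,
            "coords": seq.coords.tolist(),
            "subject_id": seq.subject_id,
            "segment_id": seq.segment_id,
        }
        path.write_text(json.dumps(payload))
    else:
        rows = []
        for f in range(seq.n_frames):
            for name in names:
                x, y, z = seq.coords[f, seq.joint_map[name], :]
                rows.append((f, name, x, y, z))
        pd.DataFrame(rows, columns=["frame", "joint", "x", "y", "z"]).to_csv(
            path, index=False)
    return path


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(seq: PoseSequence, target_fs: float) -> PoseSequence:
    """Linearly resample a sequence onto a uniform grid at ``target_fs``.

    Used to match gold-standard optical capture (100 Hz) to the video rate
    (30 Hz).  Per joint and axis the coordinates are linearly interpolated
    over the original duration; linear signals are reproduced exactly.
    """
    if not target_fs > 0:
        raise ParameterError(f"target_fs must be positive, got {target_fs}")
    if seq.n_frames < 2:
        raise InsufficientDataError("resampling needs at least 2 frames")
    # frame count scales with the rate ratio; a grid point falling past
    # the final input sample (< one input frame period) holds its value
    n_out = max(2, int(round(seq.n_frames * target_fs / seq.fs)))
    t_out = np.arange(n_out) / target_fs
    t_in = seq.times
    flat = seq.coords.reshape(seq.n_frames, -1)
    out = np.empty((n_out, flat.shape[1]))
    for c in range(flat.shape[1]):
        out[:, c] = np.interp(t_out, t_in, flat[:, c])
    return replace(seq, coords=out.reshape(n_out, seq.n_joints, 3), fs=float(target_fs))


# ---------------------------------------------------------------------------
# Gait feature sets and feature tables
# ---------------------------------------------------------------------------

@dataclass
class GaitFeatureSet:
    """The 16 named gait parameters for one walking segment."""

    features: dict[str, float]
    subject_id: str | None = None
    segment_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.features) - set(FEATURE_NAMES)
        if unknown:
            raise ParameterError(f"unknown feature names: {sorted(unknown)}")

    def __getitem__(self, name: str) -> float:
        return self.features[name]

    def to_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "subject_id": self.subject_id,
            "segment_id": self.segment_id,
            "group": self.group,
        }
        row.update({name: self.features.get(name, math.nan) for name in FEATURE_NAMES})
        return row


def features_to_table(feature_sets: list[GaitFeatureSet]) -> pd.DataFrame:
    """Stack per-segment feature sets into a feature table."""
    return pd.DataFrame([fs.to_row() for fs in feature_sets])


def validate_feature_table(df: pd.DataFrame, require_triplets: bool = False) -> pd.DataFrame:
    """Check feature-table invariants; returns the table unchanged.

    ``require_triplets`` additionally enforces exactly three segments per
    subject, the layout a reliability analysis needs.
    """
    needed = ["subject_id", "segment_id", "group", *FEATURE_NAMES]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ParseError(f"feature table missing columns: {', '.join(missing)}")
    dupes = df.duplicated(subset=["subject_id", "segment_id"])
    if dupes.any():
        raise ParseError("duplicated (subject_id, segment_id) pairs in feature table")
    bad_groups = set(df["group"].dropna()) - set(GROUPS)
    if bad_groups:
        raise ParseError(f"unknown group labels: {sorted(bad_groups)}")
    if require_triplets:
        counts = df.groupby("subject_id").size()
        off = counts[counts != 3]
        if len(off):
            raise ParseError("subjects without exactly 3 segments: "
                             f"{', '.join(map(str, off.index))}")
    return df


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path)
    return validate_feature_table(df)


def write_feature_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path
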