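"""Skeleton-sequence container, CSV I/O and low-pass filtering.

A trial is a time series of 3-D positions for a set of named body landmarks
tracked by a marker-less depth sensor (Kinect V2 vocabulary, 30 Hz nominal).
Coordinates are meters in a sensor-centered right-handed frame (x right,
y up, z toward the subject); only relative geometry (joint angles) is
consumed downstream, so any consistent right-handed frame is acceptable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal

#: Canonical landmark vocabulary (Kinect V2 joint names, lower-cased).
CANONICAL_LANDMARKS = frozenset({
    "shoulder_left", "elbow_left", "wrist_left", "hand_left",
    "shoulder_right", "elbow_right", "wrist_right", "hand_right",
    "spine_shoulder", "spine_mid",
    "hip_left", "hip_right", "knee_left", "knee_right",
})

#: Minimal landmark set a scoring run needs for a given affected side.
def required_landmarks(side: str) -> frozenset[str]:
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    other = "right" if side == "left" else "left"
    return frozenset({
        f"shoulder_{side}", f"elbow_{side}", f"wrist_{side}", f"hand_{side}",
        f"shoulder_{other}",          # contralateral shoulder fixes the frontal axis
        "spine_shoulder", "spine_mid",
        f"hip_{side}",
    })


@dataclass
class SkeletonSequence:
    """One recorded trial: positions[i, j] is landmark ``landmarks[j]`` at ``t[i]``.

    Parameters
    ----------
    t : (n,) array of time stamps in seconds, strictly increasing.
    landmarks : ordered landmark names shared by every frame.
    positions : (n, n_landmarks, 3) array of positions in meters.
    sample_rate : nominal sampling rate in Hz (30 for Kinect V2).
    side : affected body side, ``'left'`` or ``'right'``.
    meta : free-form trial annotations (subject id, test id, ...).
    """

    t: np.ndarray
    landmarks: list[str]
    positions: np.ndarray
    sample_rate: float = 30.0
    side: str = "right"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.t.ndim != 1:
            raise ValueError("t must be 1-D")
        n, m = len(self.t), len(self.landmarks)
        if self.positions.shape != (n, m, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} != ({n}, {m}, 3)")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time stamps must be strictly increasing")
        if len(set(self.landmarks)) != m:
            raise ValueError("duplicate landmark names")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def index(self, landmark: str) -> int:
        try:
            return self.landmarks.index(landmark)
        except ValueError:
            raise KeyError(f"landmark {landmark!r} not in sequence") from None

    def traj(self, landmark: str) -> np.ndarray:
        """(n, 3) position trajectory of one landmark."""
        return self.positions[:, self.index(landmark), :]

    def require(self, names) -> None:
        """Hard-fail with the missing landmark named."""
        missing = sorted(set(names) - set(self.landmarks))
        if missing:
            raise KeyError(f"sequence lacks required landmark(s): {', '.join(missing)}")


def _normalize_name(name: str) -> str:
    out = name.strip().lower().replace(" ", "_").replace("-", "_")
    # tolerate CamelCase Kinect SDK spellings like "SpineShoulder", "ElbowLeft"
    if out not in CANONICAL_LANDMARKS and name.strip():
        raw = name.strip()
        parts, cur = [], raw[0]
        for ch in raw[1:]:
            if ch.isupper():
                parts.append(cur)
                cur = ch
            else:
                cur += ch
        parts.append(cur)
        cam = "_".join(p.lower() for p in parts)
        if cam in CANONICAL_LANDMARKS:
            return cam
    return out


def _load_sidecar(path: Path) -> dict:
    for ext in (".yaml", ".yml", ".json"):
        side = path.with_suffix(ext)
        if side.exists() and side != path:
            text = side.read_text()
            return (json.loads(text) if ext == ".json" else yaml.safe_load(text)) or {}
    return {}


def read_joint_csv(path, side: str | None = None,
                   required: set[str] | None = None) -> SkeletonSequence:
    """Read a long-format trajectory CSV (columns ``time,landmark,x,y,z``).

    An optional ``side`` column, or a sidecar YAML/JSON file with the same
    stem (keys ``side``, ``sample_rate``, plus free-form metadata), supplies
    trial annotations. ``required`` landmarks missing from the file raise a
    ``KeyError`` naming them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    need_cols = {"time", "landmark", "x", "y", "z"}
    if not need_cols <= set(df.columns):
        raise ValueError(f"CSV must have columns {sorted(need_cols)}, "
                         f"got {list(df.columns)}")
    meta = _load_sidecar(path)
    if side is None:
        if "side" in df.columns:
            side = str(df["side"].iloc[0])
        else:
            side = meta.get("side", "right")
    sample_rate = float(meta.get("sample_rate", 30.0))

    df = df.copy()
    df["landmark"] = df["landmark"].map(_normalize_name)
    if df.duplicated(["time", "landmark"]).any():
        raise ValueError("duplicated time stamp for a landmark")
    times = df["time"].drop_duplicates().to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("time stamps are not strictly increasing")
    landmarks = sorted(df["landmark"].unique())

    wide = df.pivot(index="time", columns="landmark", values=["x", "y", "z"])
    if wide.isna().any().any():
        bad = sorted({lm for (_, lm) in wide.columns[wide.isna().any(axis=0)]})
        raise ValueError(f"inconsistent landmark set across frames: {bad}")

    n = len(times)
    positions = np.empty((n, len(landmarks), 3))
    for j, lm in enumerate(landmarks):
        for k, ax in enumerate(("x", "y", "z")):
            positions[:, j, k] = wide[(ax, lm)].to_numpy()

    seq = SkeletonSequence(t=times, landmarks=landmarks, positions=positions,
                           sample_rate=sample_rate, side=side,
                           meta={k: v for k, v in meta.items()
                                 if k not in ("side", "sample_rate")})
    if required is not None:
        seq.require(required)
    return seq


def write_joint_csv(seq: SkeletonSequence, path) -> None:
    """Write the long-format CSV dialect that :func:`read_joint_csv` reads."""
    rows = {
        "time": np.repeat(seq.t, len(seq.landmarks)),
        "landmark": np.tile(np.asarray(seq.landmarks, dtype=object), len(seq)),
        "x": seq.positions[:, :, 0].ravel(),
        "y": seq.positions[:, :, 1].ravel(),
        "z": seq.positions[:, :, 2].ravel(),
        "side": seq.side,
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def lowpass_filter(seq: SkeletonSequence, cutoff: float = 10.0,
                   order: int = 3) -> SkeletonSequence:
    """Zero-phase Butterworth low-pass filter, applied per coordinate channel.

    The filter is applied forward-backward (``scipy.signal.filtfilt``) with
    odd-symmetric edge extension of length ``3 * order``, so the effective
    magnitude response is the squared Butterworth response and the pass band
    carries no phase lag. High-frequency tracking jitter above ``cutoff``
    (default 10 Hz, third order) is removed; time stamps are unchanged.
    """
    nyq = seq.sample_rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    min_frames = 2 * order + 1
    if len(seq) < min_frames:
        raise ValueError(f"need at least {min_frames} frames to filter, have {len(seq)}")
    b, a = signal.butter(order, cutoff / nyq, btype="low")
    flat = seq.positions.reshape(len(seq), -1)
    filt = signal.filtfilt(b, a, flat, axis=0, padtype="odd", padlen=3 * order)
    return replace(seq, positions=filt.reshape(seq.positions.shape).copy())
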