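"""Kinematic feature extraction for the target FMA tests.

The fuzzy scorer consumes a small per-test feature vector, all in degrees:

* ``T1`` — elbow extension ROM during the motion phase (``F_Va``).
* ``T2`` — shoulder abduction ROM (``F_Va``) plus nine posture-maintenance
  features ``F_M_1..F_M_9``: means and standard deviations of shoulder
  abduction, elbow flexion, shoulder flexion and forearm pronation over the
  onset or motion phase.
* ``T3`` — shoulder abduction ROM and shoulder inward-rotation ROM
  (``F_Vb_1``, ``F_Vb_2``).

Mean-type maintenance features are re-expressed as the absolute deviation
``|measured - desired posture angle|`` so a single "smaller is better"
membership orientation covers every ``F_M`` feature; SD features are raw
sample standard deviations.

Angle conventions (all derived from the tracked landmarks only, hence
invariant to rigid motion of the sensor frame):

* elbow flexion = 180 deg minus the interior shoulder-elbow-wrist angle
  (0 = fully extended);
* shoulder abduction = angle between the upper-arm vector (shoulder->elbow)
  and the trunk axis (spine_shoulder->spine_mid);
* shoulder flexion = elevation of the upper arm within the sagittal plane
  (trunk axis x body-forward axis);
* shoulder inward rotation / forearm pronation = signed axial rotation of
  the distal segment about the proximal segment axis, measured against the
  body-forward axis (derived from the trunk and shoulder landmarks)
  projected onto the rotation plane. The forward axis is used because it
  stays nearly perpendicular to both rotation axes throughout these
  movements, so the projection never degenerates; inward / pronation is
  positive for the affected side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .skeleton import SkeletonSequence

DEG = 180.0 / np.pi

TEST_IDS = ("T1", "T2", "T3")

#: Feature indices of each target test, in canonical order.
TEST_FEATURES = {
    "T1": ("F_Va",),
    "T2": ("F_Va", "F_M_1", "F_M_2", "F_M_3", "F_M_4", "F_M_5",
           "F_M_6", "F_M_7", "F_M_8", "F_M_9"),
    "T3": ("F_Vb_1", "F_Vb_2"),
}


@dataclass
class AngleTrajectory:
    """A named joint-angle time series in degrees.

    ``value`` may contain NaN where the angle was geometrically undefined
    (degenerate axial projection); such samples are excluded from reductions.
    """

    name: str
    t: np.ndarray
    value: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.shape != self.value.shape:
            raise ValueError("t and value must have equal length")

    def window_mask(self, window) -> np.ndarray:
        t0, t1 = window
        return (self.t >= t0) & (self.t < t1) & np.isfinite(self.value)


@dataclass
class PhaseWindows:
    """Half-open onset and motion windows ``[t_start, t_end)`` in seconds."""

    onset: tuple[float, float]
    motion: tuple[float, float]

    def __post_init__(self):
        if not (self.onset[0] <= self.onset[1] <= self.motion[0] <= self.motion[1]):
            raise ValueError(f"onset {self.onset} must precede motion {self.motion}")


@dataclass
class FeatureVector:
    """Fuzzy input variables of one trial, keyed by feature index, degrees."""

    test_id: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.test_id not in TEST_FEATURES:
            raise ValueError(f"unknown test_id {self.test_id!r}")
        expected = set(TEST_FEATURES[self.test_id])
        got = set(self.values)
        if got != expected:
            raise ValueError(
                f"{self.test_id} requires features {sorted(expected)}, got {sorted(got)}")
        for k, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"feature {k} is not finite: {v}")
            if v < 0:
                raise ValueError(f"feature {k} must be >= 0, got {v}")

    def __getitem__(self, key: str) -> float:
        return self.values[key]


# ---------------------------------------------------------------- primitives

def three_point_angle(a, b, c) -> float:
    """Interior angle at ``b`` between rays b->a and b->c, degrees in [0, 180]."""
    u = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    v = np.asarray(c, dtype=float) - np.asarray(b, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-length segment in three-point angle")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _three_point_angle_series(a, b, c):
    u = a - b
    v = c - b
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu == 0) or np.any(nv == 0):
        raise ValueError("zero-length segment in three-point angle")
    cosang = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def axial_rotation_angle(proximal_pair, distal_pair, reference,
                         min_projection: float = 1e-6) -> float:
    """Signed rotation of the distal segment about the proximal segment axis.

    The distal vector and the ``reference`` direction are both projected onto
    the plane normal to the proximal axis; the result is the signed angle
    (degrees) from the projected reference to the projected distal vector,
    positive for a right-handed rotation about the proximal axis. Returns NaN
    when either projection is shorter than ``min_projection`` times the
    vector norm (distal parallel to the axis: rotation undefined).
    """
    p0, p1 = (np.asarray(p, dtype=float) for p in proximal_pair)
    d0, d1 = (np.asarray(p, dtype=float) for p in distal_pair)
    axis = p1 - p0
    na = np.linalg.norm(axis)
    if na == 0:
        raise ValueError("zero-length proximal segment")
    axis = axis / na
    dist = d1 - d0
    nd = np.linalg.norm(dist)
    if nd == 0:
        raise ValueError("zero-length distal segment")
    ref = np.asarray(reference, dtype=float)
    nr = np.linalg.norm(ref)
    if nr == 0:
        raise ValueError("zero-length reference vector")

    d_perp = dist - np.dot(dist, axis) * axis
    r_perp = ref - np.dot(ref, axis) * axis
    if np.linalg.norm(d_perp) < min_projection * nd or \
       np.linalg.norm(r_perp) < min_projection * nr:
        return float("nan")
    sin = np.dot(axis, np.cross(r_perp, d_perp))
    cos = np.dot(r_perp, d_perp)
    return float(np.degrees(np.arctan2(sin, cos)))


def segment_phases(traj: AngleTrajectory, rest_fraction: float = 0.1,
                   threshold_fraction: float = 0.05,
                   min_threshold_deg: float = 2.0) -> PhaseWindows:
    """Split a trial into onset (pre-movement baseline) and motion windows.

    The baseline is the mean of the primary angle over the initial
    ``rest_fraction`` of the trial. The onset window ends when the angle
    first departs the baseline by more than ``threshold_fraction`` of its
    total excursion (but never less than ``min_threshold_deg``, so sensor
    jitter cannot trigger a departure); the motion window runs from that
    departure to the time of peak excursion. A flat trajectory (excursion
    below ``min_threshold_deg``) yields the initial rest window as onset and
    the full trial as motion, with a warning.
    """
    t, v = traj.t, traj.value
    ok = np.isfinite(v)
    if ok.sum() < 2 or (t[-1] - t[0]) < 1.0:
        raise ValueError("trajectory must span at least 1 s with >= 2 valid samples")
    t0, t_end = float(t[0]), float(t[-1])
    n_rest = max(2, int(np.ceil(rest_fraction * ok.sum())))
    rest_idx = np.flatnonzero(ok)[:n_rest]
    baseline = float(np.mean(v[rest_idx]))
    dev = np.where(ok, np.abs(v - baseline), 0.0)
    excursion = dev.max()
    t_rest_end = float(t[rest_idx[-1]]) + np.spacing(t_end)
    if excursion <= min_threshold_deg:
        warnings.warn(f"{traj.name}: flat trajectory (excursion "
                      f"{excursion:.2f} deg); using the full trial as the "
                      "motion window")
        return PhaseWindows(onset=(t0, t_rest_end),
                            motion=(t_rest_end, t_end + np.spacing(t_end)))
    thr = max(threshold_fraction * excursion, min_threshold_deg)
    above = np.flatnonzero(dev > thr)
    i_dep = int(min(max(above[0], 2), len(t) - 2))   # keep both windows sampled
    i_peak = max(int(np.argmax(dev)), i_dep + 1)
    t_dep = float(t[i_dep])
    t_peak = float(t[min(i_peak, len(t) - 1)])
    return PhaseWindows(onset=(t0, t_dep),
                        motion=(t_dep, t_peak + np.spacing(t_peak)))


def rom(traj: AngleTrajectory, window) -> float:
    """Range of motion (max minus min, degrees) of the angle within ``window``."""
    m = traj.window_mask(window)
    if not m.any():
        raise ValueError(f"empty window {window} for trajectory {traj.name!r}")
    vals = traj.value[m]
    return float(vals.max() - vals.min())


def summary_stat(traj: AngleTrajectory, window, stat: str) -> float:
    """Arithmetic mean or sample standard deviation within ``window``."""
    m = traj.window_mask(window)
    vals = traj.value[m]
    if stat == "mean":
        if len(vals) < 1:
            raise ValueError(f"empty window {window} for trajectory {traj.name!r}")
        return float(vals.mean())
    if stat == "sd":
        if len(vals) < 2:
            raise ValueError("sample SD requires at least 2 samples")
        return float(vals.std(ddof=1))
    raise ValueError(f"stat must be 'mean' or 'sd', got {stat!r}")


# ------------------------------------------------------- angle trajectories

def _side_landmarks(seq: SkeletonSequence):
    s = seq.side
    other = "right" if s == "left" else "left"
    return {
        "shoulder": seq.traj(f"shoulder_{s}"),
        "elbow": seq.traj(f"elbow_{s}"),
        "wrist": seq.traj(f"wrist_{s}"),
        "hand": seq.traj(f"hand_{s}") if f"hand_{s}" in seq.landmarks else None,
        "shoulder_other": seq.traj(f"shoulder_{other}"),
        "spine_shoulder": seq.traj("spine_shoulder"),
        "spine_mid": seq.traj("spine_mid"),
    }


def _unit(v, axis=-1):
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    return v / np.where(n == 0, 1.0, n)


def elbow_flexion_trajectory(seq: SkeletonSequence) -> AngleTrajectory:
    """Elbow flexion angle: 0 = arm fully extended, 180 = fully flexed."""
    L = _side_landmarks(seq)
    interior = _three_point_angle_series(L["shoulder"], L["elbow"], L["wrist"])
    return AngleTrajectory("elbow_flexion", seq.t, 180.0 - interior)


def elbow_angle_trajectory(seq: SkeletonSequence) -> AngleTrajectory:
    """Interior shoulder-elbow-wrist angle (extension ROM source for T1)."""
    L = _side_landmarks(seq)
    interior = _three_point_angle_series(L["shoulder"], L["elbow"], L["wrist"])
    return AngleTrajectory("elbow", seq.t, interior)


def shoulder_abduction_trajectory(seq: SkeletonSequence) -> AngleTrajectory:
    """Elevation of the upper arm away from the trunk axis, 0 = arm at side."""
    L = _side_landmarks(seq)
    arm = L["elbow"] - L["shoulder"]
    trunk_down = L["spine_mid"] - L["spine_shoulder"]
    ang = _three_point_angle_series(L["elbow"],
                                    L["shoulder"],
                                    L["shoulder"] + trunk_down)
    return AngleTrajectory("shoulder_abduction", seq.t, ang)


def _body_axes(seq: SkeletonSequence):
    """Per-frame (down, lateral, forward) unit axes of the trunk frame.

    down: trunk axis; lateral: medial->lateral toward the affected side,
    orthogonalized against down; forward: their cross product, oriented the
    same way for either affected side.
    """
    L = _side_landmarks(seq)
    down = _unit(L["spine_mid"] - L["spine_shoulder"])
    lat = L["shoulder"] - L["shoulder_other"]          # medial->lateral, affected side
    lat = _unit(lat - np.einsum("ij,ij->i", lat, down)[:, None] * down)
    forward = np.cross(down, lat) if seq.side == "right" else np.cross(lat, down)
    return down, lat, forward


def shoulder_flexion_trajectory(seq: SkeletonSequence) -> AngleTrajectory:
    """Upper-arm elevation within the sagittal plane (forward positive)."""
    L = _side_landmarks(seq)
    down, lat, forward = _body_axes(seq)
    arm = L["elbow"] - L["shoulder"]
    arm_sag = arm - np.einsum("ij,ij->i", arm, lat)[:, None] * lat
    comp_f = np.einsum("ij,ij->i", arm_sag, forward)
    comp_d = np.einsum("ij,ij->i", arm_sag, down)
    ang = np.degrees(np.arctan2(comp_f, comp_d))
    return AngleTrajectory("shoulder_flexion", seq.t, ang)


def _axial_series(seq, prox0, prox1, dist0, dist1, sign):
    _, _, forward = _body_axes(seq)
    n = len(seq)
    out = np.empty(n)
    for i in range(n):
        out[i] = axial_rotation_angle((prox0[i], prox1[i]), (dist0[i], dist1[i]),
                                      forward[i])
    return sign * out


def shoulder_rotation_trajectory(seq: SkeletonSequence) -> AngleTrajectory:
    """Signed humeral axial rotation (inward positive for the affected side).

    The forearm (elbow->wrist) acts as the pointer; well-defined only when
    the elbow is flexed. Degenerate samples (forearm parallel to the humeral
    axis) are NaN and excluded downstream.
    """
    L = _side_landmarks(seq)
    sign = 1.0 if seq.side == "right" else -1.0
    vals = _axial_series(seq, L["shoulder"], L["elbow"], L["elbow"], L["wrist"], sign)
    return AngleTrajectory("shoulder_rotation", seq.t, vals)


def forearm_pronation_trajectory(seq: SkeletonSequence) -> AngleTrajectory:
    """Signed forearm axial rotation using the hand landmark as the pointer."""
    L = _side_landmarks(seq)
    if L["hand"] is None:
        raise KeyError(f"sequence lacks required landmark(s): hand_{seq.side}")
    sign = 1.0 if seq.side == "right" else -1.0
    vals = _axial_series(seq, L["elbow"], L["wrist"], L["wrist"], L["hand"], sign)
    return AngleTrajectory("forearm_pronation", seq.t, vals)


#: Primary trajectory whose excursion defines the onset/motion phases.
_PRIMARY = {
    "T1": elbow_angle_trajectory,
    "T2": shoulder_abduction_trajectory,
    "T3": shoulder_abduction_trajectory,
}

_T1_LANDMARKS = ("shoulder", "elbow", "wrist")
_T23_LANDMARKS = ("shoulder", "elbow", "wrist", "spine_shoulder", "spine_mid")


def _check_degenerate(traj: AngleTrajectory, window, max_bad: float = 0.5):
    t0, t1 = window
    m = (traj.t >= t0) & (traj.t < t1)
    if not m.any():
        raise ValueError(f"empty window {window} for trajectory {traj.name!r}")
    frac_bad = np.mean(~np.isfinite(traj.value[m]))
    if frac_bad > max_bad:
        raise ValueError(
            f"{traj.name}: {frac_bad:.0%} of samples in {window} are degenerate")


def extract_features(seq: SkeletonSequence, test_id: str,
                     desired_posture: dict[str, float] | None = None,
                     rest_fraction: float = 0.1,
                     threshold_fraction: float = 0.05) -> FeatureVector:
    """Compute the fuzzy input variables of one trial.

    ``desired_posture`` maps maintenance channels to the instructed posture
    angle in degrees (defaults: zero for every channel); mean-type F_M
    features are returned as absolute deviations from these.
    """
    if test_id not in TEST_FEATURES:
        raise ValueError(f"unknown test_id {test_id!r}")
    side = seq.side
    need = {f"{n}_{side}" if n in ("shoulder", "elbow", "wrist", "hand") else n
            for n in (_T1_LANDMARKS if test_id == "T1" else _T23_LANDMARKS)}
    if test_id == "T2":
        need.add(f"hand_{side}")
        need.add(f"shoulder_{'right' if side == 'left' else 'left'}")
    if test_id == "T3":
        need.add(f"shoulder_{'right' if side == 'left' else 'left'}")
    seq.require(need)
    desired = dict.fromkeys(
        ("abduction_onset", "elbow_flexion_onset", "shoulder_flexion_onset",
         "elbow_flexion_motion", "pronation_motion"), 0.0)
    if desired_posture:
        unknown = set(desired_posture) - set(desired)
        if unknown:
            raise ValueError(f"unknown desired-posture channels: {sorted(unknown)}")
        desired.update(desired_posture)

    primary = _PRIMARY[test_id](seq)
    phases = segment_phases(primary, rest_fraction, threshold_fraction)
    onset, motion = phases.onset, phases.motion
    # ROM = peak excursion relative to the resting baseline, so the range is
    # taken from trial start through the peak (the motion window alone would
    # clip the sub-threshold part of the rise off the range)
    rom_window = (onset[0], motion[1])

    if test_id == "T1":
        return FeatureVector("T1", {"F_Va": rom(primary, rom_window)})

    if test_id == "T3":
        rot = shoulder_rotation_trajectory(seq)
        _check_degenerate(rot, motion)
        return FeatureVector("T3", {
            "F_Vb_1": rom(primary, rom_window),
            "F_Vb_2": rom(rot, rom_window),
        })

    # T2: shoulder abduction with posture constraints
    abd = primary
    elb = elbow_flexion_trajectory(seq)
    sfl = shoulder_flexion_trajectory(seq)
    pro = forearm_pronation_trajectory(seq)
    _check_degenerate(pro, motion)
    dev = lambda x, d: abs(x - d)
    values = {
        "F_Va": rom(abd, rom_window),
        "F_M_1": dev(summary_stat(abd, onset, "mean"), desired["abduction_onset"]),
        "F_M_2": dev(summary_stat(elb, onset, "mean"), desired["elbow_flexion_onset"]),
        "F_M_3": dev(summary_stat(sfl, onset, "mean"), desired["shoulder_flexion_onset"]),
        "F_M_4": dev(summary_stat(elb, motion, "mean"), desired["elbow_flexion_motion"]),
        "F_M_5": dev(summary_stat(pro, motion, "mean"), desired["pronation_motion"]),
        "F_M_6": summary_stat(elb, onset, "sd"),
        "F_M_7": summary_stat(sfl, onset, "sd"),
        "F_M_8": summary_stat(elb, motion, "sd"),
        "F_M_9": summary_stat(pro, motion, "sd"),
    }
    return FeatureVector("T2", values)
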