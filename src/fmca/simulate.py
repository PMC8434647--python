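"""Synthetic skeleton trials emulating patients of graded ability.

A fixed torso faces the sensor one meter away; the affected arm is a
shoulder-elbow-wrist-hand chain driven by joint-angle commands (abduction,
flexion, elbow flexion, humeral internal rotation, forearm pronation). Each
trial holds a 1 s resting baseline, then moves along a minimum-jerk profile
to an excursion of ``ability`` times the test's desired feature value, and
holds the end posture. Posture compensation (T2) injects constant angular
deviations into the maintenance channels during the commanded phases.
Landmark output adds a per-trial constant bias of the published Kinect V2
mean-error magnitude in a random direction plus i.i.d. per-frame Gaussian
noise with the published SDs (both scaled by ``noise_scale``).

What this emulates — and what it does not: graded voluntary ROM,
compensatory posture drift and sensor noise are represented; spasticity,
tremor, movement-time variability and marker occlusion are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import TEST_FEATURES
from .config import ScoringConfig, default_config
from .skeleton import SkeletonSequence

#: Noise magnitudes (cm) per landmark family: (mean bias, per-frame SD).
LANDMARK_NOISE_CM = {
    "shoulder": (1.0, 1.0),
    "elbow": (2.0, 1.0),
    "wrist": (2.0, 1.0),
    "hand": (2.0, 1.0),          # not separately published; wrist-like
    "spine_shoulder": (1.0, 1.0),
    "spine_mid": (1.0, 1.0),
}

#: Segment lengths (m): reference anthropometry.
UPPER_ARM = 0.272
LOWER_ARM = 0.294
TORSO = 0.901
HAND_OFFSET = 0.08
SHOULDER_HALF_WIDTH = 0.18


@dataclass
class PatientProfile:
    """Movement repertoire of one simulated patient for one trial.

    ability : fraction in [0, 1] of the desired excursion achieved, either a
        scalar (applied to every commanded feature) or a per-feature map.
    compensation : constant posture deviations in degrees injected into the
        maintenance channels; keys among {'abduction_onset',
        'elbow_flexion_onset', 'shoulder_flexion_onset',
        'elbow_flexion_motion', 'pronation_motion'}.
    noise_scale : multiplier on the published landmark noise magnitudes.
    """

    ability: float | dict[str, float] = 1.0
    compensation: dict[str, float] = field(default_factory=dict)
    noise_scale: float = 0.0
    seed: int = 0
    side: str = "right"

    def __post_init__(self):
        vals = (self.ability.values() if isinstance(self.ability, dict)
                else [self.ability])
        for v in vals:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"ability must lie in [0, 1], got {v}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")

    def ability_for(self, feature: str) -> float:
        if isinstance(self.ability, dict):
            return float(self.ability.get(feature, 1.0))
        return float(self.ability)


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile s(tau) on [0, 1], s(0)=0, s(1)=1."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _rot(axis: np.ndarray, deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    th = np.radians(deg)
    k = axis / np.linalg.norm(axis)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


# Body frame (sensor coordinates, subject facing the sensor at z = +1 m):
_DOWN = np.array([0.0, -1.0, 0.0])
_FORWARD = np.array([0.0, 0.0, -1.0])       # toward the sensor


def _arm_chain(side: str, abduction: float, flexion: float, elbow_flex: float,
               internal_rot: float, pronation: float,
               shoulder: np.ndarray) -> dict[str, np.ndarray]:
    """Landmark positions of the arm for one frame of commanded angles."""
    lateral = np.array([1.0, 0.0, 0.0]) if side == "right" else np.array([-1.0, 0.0, 0.0])
    # upper arm: hang down, lift by abduction (frontal) then flexion (sagittal)
    r_ab = _rot(_FORWARD, abduction) if side == "right" else _rot(_FORWARD, -abduction)
    r_fl = _rot(lateral, -flexion) if side == "right" else _rot(lateral, flexion)
    u_arm = r_fl @ r_ab @ _DOWN
    elbow = shoulder + UPPER_ARM * u_arm

    # elbow bend axis: perpendicular to the humerus, lateral-ish
    bend = np.cross(u_arm, _FORWARD)
    if np.linalg.norm(bend) < 1e-9:
        bend = lateral
    bend = bend / np.linalg.norm(bend)
    sign_ir = -1.0 if side == "right" else 1.0     # inward positive
    r_ir = _rot(u_arm, sign_ir * internal_rot)
    u_fore = r_ir @ _rot(bend, -elbow_flex) @ u_arm
    wrist = elbow + LOWER_ARM * u_fore

    # hand marker: palm-center proxy offset perpendicular to the forearm.
    # Zero pronation aligns the offset with the body-forward axis projected
    # onto the forearm's rotation plane (the same reference the pronation
    # measurement uses), so the measured angle equals the commanded one.
    f_axis = np.cross(_DOWN, lateral) if side == "right" else np.cross(lateral, _DOWN)
    n0 = f_axis - np.dot(f_axis, u_fore) * u_fore
    if np.linalg.norm(n0) < 1e-6:
        n0 = np.cross(u_fore, lateral)
    n0 = n0 / np.linalg.norm(n0)
    sign_pr = 1.0 if side == "right" else -1.0
    hand_dir = _rot(u_fore, sign_pr * pronation) @ n0
    hand = wrist + HAND_OFFSET * hand_dir
    return {"elbow": elbow, "wrist": wrist, "hand": hand}


#: Per-test commanded channels: (rest value deg, feature driving excursion,
#: desired-value key, direction sign).
def _commands(test_id: str, profile: PatientProfile,
              desired: dict[str, float]) -> dict[str, tuple[float, float]]:
    """Map channel -> (rest angle, excursion) in degrees."""
    a = profile.ability_for
    if test_id == "T1":
        # elbow extends from a flexed start; elbow interior angle ROM = excursion
        return {"abduction": (25.0, 0.0), "flexion": (10.0, 0.0),
                "elbow_flex": (75.0, -a("F_Va") * desired["F_Va"]),
                "internal_rot": (0.0, 0.0), "pronation": (0.0, 0.0)}
    if test_id == "T2":
        return {"abduction": (0.0, a("F_Va") * desired["F_Va"]),
                "flexion": (0.0, 0.0),
                "elbow_flex": (0.0, 0.0),
                "internal_rot": (0.0, 0.0), "pronation": (0.0, 0.0)}
    if test_id == "T3":
        return {"abduction": (5.0, a("F_Vb_1") * desired["F_Vb_1"]),
                "flexion": (0.0, 0.0),
                "elbow_flex": (90.0, 0.0),
                "internal_rot": (10.0, a("F_Vb_2") * desired["F_Vb_2"]),
                "pronation": (0.0, 0.0)}
    raise ValueError(f"unknown test_id {test_id!r}")


_COMPENSATION_CHANNEL = {
    "abduction_onset": ("abduction", "onset"),
    "elbow_flexion_onset": ("elbow_flex", "onset"),
    "shoulder_flexion_onset": ("flexion", "onset"),
    "elbow_flexion_motion": ("elbow_flex", "motion"),
    "pronation_motion": ("pronation", "motion"),
}


def simulate_trial(profile: PatientProfile, test_id: str, duration: float = 6.0,
                   rate: float = 30.0, rest_duration: float = 1.0,
                   config: ScoringConfig | None = None) -> SkeletonSequence:
    """Generate one trial; deterministic for a fixed profile seed."""
    if test_id not in TEST_FEATURES:
        raise ValueError(f"unknown test_id {test_id!r}")
    config = config or default_config()
    desired = config.desired_values[test_id]
    rng = np.random.default_rng(profile.seed)
    side = profile.side

    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    move_time = max(duration - rest_duration - 1.0, 0.5)  # hold ~1 s at the end
    s = _min_jerk((t - rest_duration) / move_time)

    unknown = set(profile.compensation) - set(_COMPENSATION_CHANNEL)
    if unknown:
        raise ValueError(f"unknown compensation channels: {sorted(unknown)}")

    cmds = _commands(test_id, profile, desired)
    channels = {}
    for name, (rest, excursion) in cmds.items():
        channels[name] = rest + excursion * s
    for key, dev in profile.compensation.items():
        channel, phase = _COMPENSATION_CHANNEL[key]
        if phase == "onset":
            channels[channel] = channels[channel] + dev       # constant offset
        else:
            channels[channel] = channels[channel] + dev * s   # grows with motion

    # static torso
    spine_shoulder = np.array([0.0, 0.45, 1.0])
    spine_mid = spine_shoulder + (TORSO / 2) * _DOWN
    lat = 1.0 if side == "right" else -1.0
    shoulder = spine_shoulder + np.array([lat * SHOULDER_HALF_WIDTH, -0.02, 0.0])
    shoulder_other = spine_shoulder + np.array([-lat * SHOULDER_HALF_WIDTH, -0.02, 0.0])
    hip = spine_shoulder + TORSO * _DOWN + np.array([lat * 0.1, 0.0, 0.0])
    hip_other = spine_shoulder + TORSO * _DOWN + np.array([-lat * 0.1, 0.0, 0.0])
    knee = hip + np.array([0.0, -0.35, -0.25])
    knee_other = hip_other + np.array([0.0, -0.35, -0.25])

    other = "left" if side == "right" else "right"
    static = {
        "spine_shoulder": spine_shoulder, "spine_mid": spine_mid,
        f"shoulder_{side}": shoulder, f"shoulder_{other}": shoulder_other,
        f"hip_{side}": hip, f"hip_{other}": hip_other,
        f"knee_{side}": knee, f"knee_{other}": knee_other,
    }
    # unaffected arm rests at the side
    rest_chain = _arm_chain(other, 10.0, 5.0, 10.0, 0.0, 0.0, shoulder_other)
    for k, v in rest_chain.items():
        static[f"{k}_{other}"] = v

    landmarks = sorted(static) + [f"elbow_{side}", f"wrist_{side}", f"hand_{side}"]
    landmarks = sorted(set(landmarks))
    positions = np.empty((n, len(landmarks), 3))
    idx = {lm: j for j, lm in enumerate(landmarks)}
    for lm, pos in static.items():
        positions[:, idx[lm], :] = pos
    for i in range(n):
        chain = _arm_chain(side, channels["abduction"][i], channels["flexion"][i],
                           channels["elbow_flex"][i], channels["internal_rot"][i],
                           channels["pronation"][i], shoulder)
        for k, v in chain.items():
            positions[i, idx[f"{k}_{side}"], :] = v

    if profile.noise_scale > 0:
        for lm in landmarks:
            family = lm.rsplit("_", 1)[0] if lm.split("_")[0] in (
                "shoulder", "elbow", "wrist", "hand", "hip", "knee") else lm
            mean_cm, sd_cm = LANDMARK_NOISE_CM.get(family, (1.0, 1.0))
            bias_dir = rng.normal(size=3)
            bias_dir /= np.linalg.norm(bias_dir)
            bias = bias_dir * (mean_cm / 100.0) * profile.noise_scale
            jitter = rng.normal(scale=(sd_cm / 100.0) * profile.noise_scale,
                                size=(n, 3))
            positions[:, idx[lm], :] += bias + jitter

    return SkeletonSequence(
        t=t, landmarks=landmarks, positions=positions, sample_rate=rate,
        side=side, meta={"test_id": test_id, "seed": profile.seed,
                         "noise_scale": profile.noise_scale})


def generate_cohort(n: int, test_id: str, ability_grid=None, seed: int = 0,
                    noise_scale: float = 1.0, duration: float = 6.0,
                    config: ScoringConfig | None = None):
    """Reproducible cohort of (profile, sequence) pairs spanning abilities."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if ability_grid is None:
        ability_grid = np.linspace(0.0, 1.0, n)
    else:
        ability_grid = np.asarray(ability_grid, dtype=float)
        if len(ability_grid) != n:
            raise ValueError("ability_grid length must equal n")
    children = np.random.SeedSequence(seed).spawn(n)
    out = []
    for ability, child in zip(ability_grid, children):
        profile = PatientProfile(ability=float(ability),
                                 noise_scale=noise_scale,
                                 seed=int(child.generate_state(1)[0] % (2**31)))
        out.append((profile, simulate_trial(profile, test_id,
                                            duration=duration, config=config)))
    return out


# ------------------------------------------------------- packaged fixtures

def fixture_table8():
    """The packaged 9-subject x 3-test clinical score table."""
    from importlib import resources
    from .evaluation import ScoreTable
    with resources.as_file(resources.files("fmca.data")
                           .joinpath("table8_scores.csv")) as p:
        return ScoreTable.from_csv(p)


def fixture_table9():
    """The packaged 3x3 clinician-vs-system contingency table."""
    from .evaluation import ContingencyTable
    return ContingencyTable(np.array([[5, 0, 0], [0, 13, 0], [0, 1, 8]]))
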