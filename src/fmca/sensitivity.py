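"""Worst-case sensor-error propagation and grade resolution.

Three stages:

1. Landmark tracking error -> joint-angle error. For a three-point angle
   the worst case treats each endpoint error as a lateral displacement of
   its segment: with endpoint errors ``e`` (mean + 1 SD) and segment length
   ``L``, each segment's direction can tilt by up to ``arcsin((e1+e2)/L)``,
   and the two tilts add. Features whose error was measured directly as an
   angle (e.g. shoulder internal rotation) pass through unchanged. This
   closed form is this package's declared model; the published feature-error
   table is carried separately as a fixture.
2. Feature error -> maximum fuzzy-result error. The feature space is swept
   on a grid (exhaustive for one or two features, seeded random sampling
   otherwise); at each nominal vector the continuous score is re-evaluated
   under every +/- sign combination of the per-feature errors (clamped to
   the universe) and the largest absolute score change is recorded.
3. Fuzzy-result error -> achievable number of grades: how many disjoint
   intervals of that width fit in [0, 1], i.e. ``floor(1 / max_error)``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .scoring import TestDefinition


@dataclass
class ErrorModel:
    """Landmark tracking errors (cm), direct angular errors (deg), segment
    lengths (cm)."""

    landmark_errors: dict[str, tuple[float, float]]
    rotation_errors_deg: dict[str, float] = field(default_factory=dict)
    segment_lengths_cm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for lm, (m, s) in self.landmark_errors.items():
            if m < 0 or s < 0:
                raise ValueError(f"{lm}: error magnitudes must be >= 0")
        for name, L in self.segment_lengths_cm.items():
            if not L > 0:
                raise ValueError(f"{name}: segment length must be > 0")
        for name, e in self.rotation_errors_deg.items():
            if not e >= 0:
                raise ValueError(f"{name}: angular error must be >= 0")

    def endpoint_error(self, landmark: str) -> float:
        """Worst-case positional error (cm): mean + 1 standard deviation."""
        try:
            m, s = self.landmark_errors[landmark]
        except KeyError:
            raise KeyError(f"no tracking error for landmark {landmark!r}") from None
        return m + s

    @classmethod
    def from_yaml(cls, path) -> "ErrorModel":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            landmark_errors={k: (float(v["mean_cm"]), float(v["sd_cm"]))
                             for k, v in data["landmark_errors"].items()},
            rotation_errors_deg={k: float(v) for k, v in
                                 data.get("rotation_errors_deg", {}).items()},
            segment_lengths_cm={k: float(v) for k, v in
                                data.get("segment_lengths_cm", {}).items()},
        )


def default_error_model() -> ErrorModel:
    """The packaged Kinect V2 error model (tracking errors + anthropometry)."""
    with resources.as_file(resources.files("fmca.data")
                           .joinpath("table5_error_model.yaml")) as p:
        return ErrorModel.from_yaml(p)


def published_feature_errors() -> dict:
    """The packaged published per-feature worst-case errors and fuzzy errors."""
    with resources.as_file(resources.files("fmca.data")
                           .joinpath("table6_errors.yaml")) as p:
        return yaml.safe_load(p.read_text())


def _tilt(e1_cm: float, e2_cm: float, length_cm: float) -> float:
    ratio = (e1_cm + e2_cm) / length_cm
    if ratio > 1.0:
        warnings.warn(f"degenerate short segment: error ratio {ratio:.2f} "
                      "clamped to 1")
        ratio = 1.0
    return math.degrees(math.asin(ratio))


def worst_case_angle_error(model: ErrorModel, landmarks: tuple[str, str, str],
                           segment_lengths: tuple[float, float]) -> float:
    """Worst-case error (deg) of a three-point angle at ``landmarks[1]``.

    ``segment_lengths`` are (vertex->first, vertex->third) lengths in cm.
    """
    a, b, c = landmarks
    l1, l2 = segment_lengths
    return (_tilt(model.endpoint_error(a), model.endpoint_error(b), l1)
            + _tilt(model.endpoint_error(b), model.endpoint_error(c), l2))


def feature_error_table(model: ErrorModel) -> dict[str, dict[str, float]]:
    """Worst-case per-feature angular errors under this package's model.

    Elbow-based features propagate errors through the upper and lower arm;
    shoulder-elevation features through the torso and upper arm; the
    shoulder internal-rotation feature uses its directly measured angular
    error; pronation reuses the lower-arm geometry.
    """
    L = model.segment_lengths_cm
    elbow = worst_case_angle_error(
        model, ("shoulder", "elbow", "wrist"), (L["upper_arm"], L["lower_arm"]))
    shoulder_elev = worst_case_angle_error(
        model, ("spine_mid", "spine_shoulder", "elbow"),
        (L["torso"], L["upper_arm"]))
    rotation = model.rotation_errors_deg.get("shoulder_internal_rotation", 0.0)
    return {
        "T1": {"F_Va": elbow},
        "T2": {"F_Va": shoulder_elev,
               "F_M_1": shoulder_elev, "F_M_2": elbow, "F_M_3": shoulder_elev,
               "F_M_4": elbow, "F_M_5": elbow,
               "F_M_6": elbow, "F_M_7": shoulder_elev, "F_M_8": elbow,
               "F_M_9": elbow},
        "T3": {"F_Vb_1": shoulder_elev, "F_Vb_2": rotation},
    }


def max_fuzzy_error(testdef: TestDefinition, feature_errors: dict[str, float],
                    sweep_points: int = 201, n_random: int = 300,
                    seed: int = 0) -> float:
    """Largest |Delta FM_CA| a worst-case feature perturbation can cause.

    The nominal feature space is a full grid for one feature,
    a ``min(sweep_points, 61)``-per-axis grid for two, and ``n_random``
    seeded uniform samples otherwise. Sign combinations of the per-feature
    errors are exhaustive up to four features, else 64 seeded random sign
    vectors. Perturbed inputs are clamped to each feature's universe.
    """
    feats = list(testdef.features)
    errs = np.array([float(feature_errors[f]) for f in feats])
    if (errs < 0).any():
        raise ValueError("feature errors must be >= 0")
    betas = np.array([testdef.desired_values[f] for f in feats])
    k = len(feats)
    rng = np.random.default_rng(seed)

    if k == 1:
        nominals = np.linspace(0, betas[0], sweep_points)[:, None]
    elif k == 2:
        n = min(sweep_points, 61)
        axes = [np.linspace(0, b, n) for b in betas]
        nominals = np.stack([g.ravel() for g in np.meshgrid(*axes)], axis=1)
    else:
        nominals = rng.uniform(0, 1, size=(n_random, k)) * betas

    if k <= 4:
        signs = np.array(list(itertools.product((-1.0, 1.0), repeat=k)))
    else:
        signs = rng.choice([-1.0, 1.0], size=(64, k))

    ev = testdef.system.evaluate
    worst = 0.0
    for nom in nominals:
        base = ev(dict(zip(feats, nom)))
        for s in signs:
            pert = np.clip(nom + s * errs, 0.0, betas)
            worst = max(worst, abs(ev(dict(zip(feats, pert))) - base))
    return worst


def achievable_grades(max_error: float) -> int:
    """Disjoint intervals of width ``max_error`` that fit in [0, 1]."""
    if not 0.0 < max_error <= 1.0:
        raise ValueError("max_error must lie in (0, 1]")
    # guard against floating-point underestimates of exact divisors
    return int(math.floor(1.0 / max_error + 1e-12))


@dataclass
class SensitivityReport:
    test_id: str
    feature_errors: dict[str, float]
    max_fuzzy_error: float
    n_grades: int

    def __post_init__(self):
        if not 0.0 < self.max_fuzzy_error < 1.0:
            raise ValueError("max_fuzzy_error must lie in (0, 1)")
        if self.n_grades < 1:
            raise ValueError("n_grades must be >= 1")

    def to_dict(self) -> dict:
        return {"test_id": self.test_id,
                "feature_errors_deg": dict(self.feature_errors),
                "max_fuzzy_error": self.max_fuzzy_error,
                "n_grades": self.n_grades}


def analyze_test(testdef: TestDefinition, model: ErrorModel | None = None,
                 feature_errors: dict[str, float] | None = None,
                 sweep_points: int = 201, seed: int = 0) -> SensitivityReport:
    """Full error-propagation chain for one test.

    ``feature_errors`` (deg) may be supplied directly (e.g. the published
    table); otherwise they are derived from ``model`` via
    :func:`feature_error_table`.
    """
    if feature_errors is None:
        model = model or default_error_model()
        feature_errors = feature_error_table(model)[testdef.test_id]
    err = max_fuzzy_error(testdef, feature_errors, sweep_points=sweep_points,
                          seed=seed)
    return SensitivityReport(
        test_id=testdef.test_id,
        feature_errors={k: float(v) for k, v in feature_errors.items()},
        max_fuzzy_error=err,
        n_grades=achievable_grades(err),
    )
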