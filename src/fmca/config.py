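"""Scoring configuration: per-test desired feature values and engine knobs.

Every number a clinician might audit lives here rather than in code: the
desired feature value beta that tops each input universe (degrees; 30 for SD
features), the desired posture angles the maintenance deviations are taken
against, the crisp-scorer membership threshold tau, the output-grid
resolution, and the negated-consequent implication mode. The shipped
defaults anchor T2's abduction target at 90 deg (the instructed 0-90 deg
motion) and the SD bound at 30; the remaining targets are declared package
defaults for the instructed motions and are meant to be overridden per
deployment from YAML/JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import TEST_FEATURES

_SD_FEATURES = ("F_M_6", "F_M_7", "F_M_8", "F_M_9")


def _default_desired() -> dict[str, dict[str, float]]:
    return {
        # elbow extension ROM during hand-to-knee
        "T1": {"F_Va": 60.0},
        # shoulder abduction 0-90 deg; maintenance deviations tolerated up
        # to 30 deg, SD features bounded at 30
        "T2": {"F_Va": 90.0,
               "F_M_1": 30.0, "F_M_2": 30.0, "F_M_3": 30.0,
               "F_M_4": 30.0, "F_M_5": 30.0,
               "F_M_6": 30.0, "F_M_7": 30.0, "F_M_8": 30.0, "F_M_9": 30.0},
        # shoulder adduction / inward rotation during hand-to-knee
        "T3": {"F_Vb_1": 40.0, "F_Vb_2": 30.0},
    }


def _default_posture() -> dict[str, float]:
    return {
        "abduction_onset": 0.0,
        "elbow_flexion_onset": 0.0,
        "shoulder_flexion_onset": 0.0,
        "elbow_flexion_motion": 0.0,
        "pronation_motion": 0.0,
    }


@dataclass
class ScoringConfig:
    """Validated bundle of all tunable scoring parameters."""

    desired_values: dict[str, dict[str, float]] = field(default_factory=_default_desired)
    desired_posture: dict[str, float] = field(default_factory=_default_posture)
    tau: float = 0.5
    grid_size: int = 2001
    negated_mode: str = "complement"
    filter_cutoff_hz: float = 10.0
    filter_order: int = 3
    rest_fraction: float = 0.1
    threshold_fraction: float = 0.05

    def __post_init__(self):
        if set(self.desired_values) != set(TEST_FEATURES):
            raise ValueError(f"desired_values must cover tests "
                             f"{sorted(TEST_FEATURES)}")
        for tid, feats in self.desired_values.items():
            if set(feats) != set(TEST_FEATURES[tid]):
                raise ValueError(f"{tid}: desired_values must cover features "
                                 f"{list(TEST_FEATURES[tid])}, got {sorted(feats)}")
            for k, v in feats.items():
                if not v > 0:
                    raise ValueError(f"{tid}.{k}: desired value must be > 0")
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must lie in (0, 1)")
        if self.grid_size < 1001:
            raise ValueError("grid_size must be >= 1001")
        if self.negated_mode not in ("complement", "union"):
            raise ValueError("negated_mode must be 'complement' or 'union'")
        if not 0 < self.rest_fraction < 1 or not 0 < self.threshold_fraction < 1:
            raise ValueError("phase fractions must lie in (0, 1)")

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScoringConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "ScoringConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})


def default_config() -> ScoringConfig:
    return ScoringConfig()
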