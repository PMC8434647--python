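"""Per-test rule bases and FM-score computation.

Wires the three target FMA tests to the Mamdani engine:

* ``T1`` (elbow extension during hand to knee) — 3 rules grading a single
  three-level feature.
* ``T2`` (shoulder abduction 0-90 deg) — the T1 rules on abduction ROM plus
  two posture rules: violating an onset-phase constraint scores 0; violating
  a motion-phase constraint forbids the top score ("FM score is NOT S1").
* ``T3`` (shoulder adduction / inward rotation during hand to knee) — 3
  rules over two two-level features combined with AND/OR.

Alongside the continuous score ``FM_CA`` in [0, 1], a crisp three-point
counterpart ``FM_3A`` is produced by binarizing every atom membership at a
threshold tau and evaluating the same rules as Boolean logic, and the
extended seven-point clinician scale ``FM_7`` is mapped to integers 0..6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import ScoringConfig, default_config
from .features import TEST_FEATURES, FeatureVector
from .fuzzy import And, Atom, FuzzyRule, FuzzySetSpec, MamdaniSystem, Or

TEST_NAMES = {
    "T1": "Elbow extension during hand to knee",
    "T2": "Shoulder abduction 0-90 deg",
    "T3": "Shoulder adduction/inward rotation during hand to knee",
}

#: Input fuzzy sets available to each feature type.
FEATURE_SETS = {
    "F_Va": ("R1", "R2", "R3"),
    "F_Vb": ("R4", "R5"),
    "F_M": ("R6", "R7"),
}

FM7_SYMBOLS = ("0", "0+", "1-", "1", "1+", "2-", "2")


def feature_type(feature: str) -> str:
    if feature == "F_Va":
        return "F_Va"
    if feature.startswith("F_Vb"):
        return "F_Vb"
    if feature.startswith("F_M"):
        return "F_M"
    raise ValueError(f"unknown feature {feature!r}")


def build_rulebase(test_id: str) -> list[FuzzyRule]:
    """The canonical IF-THEN rules of one target test.

    T2's last rule nominally references an input set "R8" on F_M_8; only
    R1-R7 exist, and every sibling atom of that rule uses R7 ("not
    maintained"), so the atom is built as ``F_M_8 IS R7``.
    """
    if test_id == "T1":
        return [
            FuzzyRule(Atom("F_Va", "R1"), "S1"),
            FuzzyRule(Atom("F_Va", "R2"), "S2"),
            FuzzyRule(Atom("F_Va", "R3"), "S3"),
        ]
    if test_id == "T2":
        return build_rulebase("T1") + [
            FuzzyRule(Or(Atom("F_M_1", "R7"), Atom("F_M_2", "R7"),
                         Atom("F_M_3", "R7"), Atom("F_M_6", "R7")), "S3"),
            FuzzyRule(Or(Atom("F_M_4", "R7"), Atom("F_M_5", "R7"),
                         Atom("F_M_8", "R7"), Atom("F_M_9", "R7")),
                      "S1", negated=True),
        ]
    if test_id == "T3":
        return [
            FuzzyRule(And(Atom("F_Vb_1", "R4"), Atom("F_Vb_2", "R4")), "S1"),
            FuzzyRule(Or(Atom("F_Vb_1", "R5"), Atom("F_Vb_2", "R5")), "S2"),
            FuzzyRule(And(Atom("F_Vb_1", "R5"), Atom("F_Vb_2", "R5")), "S3"),
        ]
    raise ValueError(f"unknown test_id {test_id!r}")


@dataclass
class TestDefinition:
    """One target FMA test: features, universes, rules, and its engine."""

    test_id: str
    name: str
    features: tuple[str, ...]
    desired_values: dict[str, float]
    rules: list[FuzzyRule]
    grid_size: int = 2001
    negated_mode: str = "complement"
    system: MamdaniSystem = field(init=False, repr=False)

    def __post_init__(self):
        if tuple(self.features) != TEST_FEATURES[self.test_id]:
            raise ValueError(f"{self.test_id}: feature list must be "
                             f"{TEST_FEATURES[self.test_id]}")
        missing = set(self.features) - set(self.desired_values)
        if missing:
            raise ValueError(f"{self.test_id}: no desired value for {sorted(missing)}")
        referenced = {a.feature for r in self.rules for a in r.atoms()}
        unknown = referenced - set(self.features)
        if unknown:
            raise ValueError(f"{self.test_id}: rules reference unknown "
                             f"features {sorted(unknown)}")
        input_sets = {}
        for feat in self.features:
            beta = float(self.desired_values[feat])
            for set_idx in FEATURE_SETS[feature_type(feat)]:
                input_sets[(feat, set_idx)] = FuzzySetSpec(set_idx, 0.0, beta)
        self.system = MamdaniSystem(input_sets=input_sets, rules=self.rules,
                                    grid_size=self.grid_size,
                                    negated_mode=self.negated_mode)


def make_test_definition(test_id: str,
                         config: ScoringConfig | None = None) -> TestDefinition:
    config = config or default_config()
    return TestDefinition(
        test_id=test_id,
        name=TEST_NAMES[test_id],
        features=TEST_FEATURES[test_id],
        desired_values=dict(config.desired_values[test_id]),
        rules=build_rulebase(test_id),
        grid_size=config.grid_size,
        negated_mode=config.negated_mode,
    )


def all_test_definitions(config: ScoringConfig | None = None) -> dict[str, TestDefinition]:
    config = config or default_config()
    return {tid: make_test_definition(tid, config) for tid in TEST_FEATURES}


def score_continuous(fv: FeatureVector, testdef: TestDefinition) -> float:
    """Continuous FM score (FM_CA) in [0, 1] via full Mamdani inference."""
    if fv.test_id != testdef.test_id:
        raise ValueError(f"feature vector is for {fv.test_id}, "
                         f"test definition for {testdef.test_id}")
    return testdef.system.evaluate(fv.values)


def score_three_point(fv: FeatureVector, testdef: TestDefinition,
                      tau: float = 0.5) -> int:
    """Crisp three-point counterpart (FM_3A) of the fuzzy scorer.

    Atom memberships are binarized at ``tau`` and the rules evaluated as
    Boolean logic with a fixed precedence: any fired hard-fail rule
    (consequent S3) forces 0; otherwise a fired S1 rule gives 2 and a fired
    S2 rule gives 1; a fired "NOT S1" rule caps the result at 1; no rule
    fired gives 0.
    """
    if fv.test_id != testdef.test_id:
        raise ValueError(f"feature vector is for {fv.test_id}, "
                         f"test definition for {testdef.test_id}")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    mu = testdef.system.memberships(fv.values)
    crisp = {k: 1.0 if v >= tau else 0.0 for k, v in mu.items()}
    from .fuzzy import fire_rule
    fired = {"S1": False, "S2": False, "S3": False, "NOT_S1": False}
    for rule in testdef.rules:
        if fire_rule(rule, crisp) >= 1.0:
            fired["NOT_S1" if rule.negated else rule.consequent] = True
    if fired["S3"]:
        return 0
    score = 2 if fired["S1"] else (1 if fired["S2"] else 0)
    if fired["NOT_S1"]:
        score = min(score, 1)
    return score


def fm7_to_numeric(symbol: str) -> int:
    """Map the extended seven-point scale to integers 0..6.

    The sum conversion '1-' -> 2, '1' -> 3, '1+' -> 4, '2-' -> 5, '2' -> 6
    extends naturally with '0' -> 0 and '0+' -> 1. A Unicode minus is
    accepted as '-'.
    """
    s = str(symbol).strip().replace("−", "-")
    try:
        return FM7_SYMBOLS.index(s)
    except ValueError:
        raise ValueError(f"unknown FM_7 symbol {symbol!r}; "
                         f"expected one of {FM7_SYMBOLS}") from None
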