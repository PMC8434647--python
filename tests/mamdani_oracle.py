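"""Independent brute-force Mamdani implementation used as a test oracle.

Deliberately separate from the package code path: rules are re-encoded as
literal nested tuples, membership functions are written out piecewise, and
defuzzification integrates on a very dense grid. Only numpy is shared.
"""

import numpy as np

# rule encoding: (antecedent, consequent, negated) where antecedent is
# ('atom', feature, set) | ('and'|'or', [antecedents...])
ORACLE_RULES = {
    "T1": [
        (("atom", "F_Va", "R1"), "S1", False),
        (("atom", "F_Va", "R2"), "S2", False),
        (("atom", "F_Va", "R3"), "S3", False),
    ],
    "T2": [
        (("atom", "F_Va", "R1"), "S1", False),
        (("atom", "F_Va", "R2"), "S2", False),
        (("atom", "F_Va", "R3"), "S3", False),
        (("or", [("atom", "F_M_1", "R7"), ("atom", "F_M_2", "R7"),
                 ("atom", "F_M_3", "R7"), ("atom", "F_M_6", "R7")]), "S3", False),
        (("or", [("atom", "F_M_4", "R7"), ("atom", "F_M_5", "R7"),
                 ("atom", "F_M_8", "R7"), ("atom", "F_M_9", "R7")]), "S1", True),
    ],
    "T3": [
        (("and", [("atom", "F_Vb_1", "R4"), ("atom", "F_Vb_2", "R4")]), "S1", False),
        (("or", [("atom", "F_Vb_1", "R5"), ("atom", "F_Vb_2", "R5")]), "S2", False),
        (("and", [("atom", "F_Vb_1", "R5"), ("atom", "F_Vb_2", "R5")]), "S3", False),
    ],
}


def input_mu(set_index: str, x: float, beta: float) -> float:
    x = min(max(x, 0.0), beta)
    if set_index in ("R1", "R4", "R7"):
        return x / beta
    if set_index in ("R3", "R5", "R6"):
        return 1.0 - x / beta
    if set_index == "R2":
        return x / (beta / 2) if x <= beta / 2 else (beta - x) / (beta / 2)
    raise ValueError(set_index)


def output_mu(set_index: str, y: np.ndarray) -> np.ndarray:
    if set_index == "S1":
        return np.where(y >= 0.5, (y - 0.5) / 0.5, 0.0)
    if set_index == "S2":
        return np.where(y <= 0.5, y / 0.5, (1.0 - y) / 0.5)
    if set_index == "S3":
        return np.where(y <= 0.5, (0.5 - y) / 0.5, 0.0)
    raise ValueError(set_index)


def _strength(node, features, betas) -> float:
    kind = node[0]
    if kind == "atom":
        _, feat, set_index = node
        return input_mu(set_index, features[feat], betas[feat])
    op = min if kind == "and" else max
    return op(_strength(child, features, betas) for child in node[1])


def oracle_fm_ca(test_id: str, features: dict, betas: dict,
                 n_grid: int = 200_001) -> float:
    """Normalized crisp score by dense-grid max-aggregation and centroid."""
    y = np.linspace(0.0, 1.0, n_grid)
    agg = np.zeros_like(y)
    for antecedent, consequent, negated in ORACLE_RULES[test_id]:
        s = _strength(antecedent, features, betas)
        mu = output_mu(consequent, y)
        if negated:
            mu = 1.0 - mu
        agg = np.maximum(agg, np.minimum(s, mu))
    area = np.trapezoid(agg, y)
    if area <= 0:
        raise ValueError("no rule fired")
    c = np.trapezoid(y * agg, y) / area
    c_lo = 1.0 / 6.0
    c_hi = 5.0 / 6.0
    return float((c - c_lo) / (c_hi - c_lo))
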