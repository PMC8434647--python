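"""Generic Mamdani fuzzy inference with triangular membership functions.

Fuzzification uses triangular/ramp membership functions on a per-feature
universe of discourse [alpha, beta] (alpha = 0; beta = the desired feature
value of the instructed motion, or 30 for SD features). Rule antecedents
combine atom memberships with min (AND) / max (OR); rule firing truncates
(min) the consequent output set; truncated sets are aggregated pointwise by
max; the crisp result is the centroid (center of area) of the aggregate on
the output universe [0, 1], then linearly rescaled so that a fully-fired
lowest set maps to 0 and a fully-fired highest set maps to 1.

Input set roles
---------------
Three-level features (``F_Va``): R1 "performed fully" rises linearly 0 -> 1
over [0, beta]; R2 "performed partially" is a symmetric triangle peaking at
beta/2; R3 "not performed" is the pointwise complement of R1. Two-level
features reuse the ramp pair: R4/R5 ("performed"/"not performed") for
``F_Vb``, and R6/R7 ("maintained"/"not maintained") for ``F_M``. F_M inputs
are deviations, so R6 is the *falling* ramp (zero deviation = fully
maintained) and R7 its complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: role -> (is_rising_ramp, is_triangle); complements handled explicitly
INPUT_ROLES = {
    "R1": "ramp_up",      # performed fully
    "R2": "triangle",     # performed partially
    "R3": "ramp_down",    # not performed (complement of R1)
    "R4": "ramp_up",      # performed
    "R5": "ramp_down",    # not performed (complement of R4)
    "R6": "ramp_down",    # maintained (input is a deviation: small -> 1)
    "R7": "ramp_up",      # not maintained (complement of R6)
}

OUTPUT_VERTICES = {"S1": 1.0, "S2": 0.5, "S3": 0.0}


@dataclass(frozen=True)
class FuzzySetSpec:
    """Input fuzzy set on the universe [alpha, beta] of one feature."""

    index: str                 # R1..R7
    alpha: float = 0.0
    beta: float = 1.0

    def __post_init__(self):
        if self.index not in INPUT_ROLES:
            raise ValueError(f"unknown input set {self.index!r}")
        if not self.beta > self.alpha:
            raise ValueError("beta must exceed alpha")

    def membership(self, value) -> np.ndarray | float:
        """Degree of membership in [0, 1]; input clamped to the universe."""
        x = np.clip(np.asarray(value, dtype=float), self.alpha, self.beta)
        u = (x - self.alpha) / (self.beta - self.alpha)
        role = INPUT_ROLES[self.index]
        if role == "ramp_up":
            mu = u
        elif role == "ramp_down":
            mu = 1.0 - u
        else:  # symmetric triangle peaking at the universe midpoint
            mu = 1.0 - np.abs(2.0 * u - 1.0)
        return mu if mu.ndim else float(mu)


@dataclass(frozen=True)
class OutputSetSpec:
    """Triangular output set on [gamma, delta] = [0, 1].

    S1/S2/S3 peak at 1, 0.5 and 0 respectively, each with half-width half
    the output range, mirroring the three-level FM score 2/1/0.
    """

    index: str
    gamma: float = 0.0
    delta: float = 1.0

    def __post_init__(self):
        if self.index not in OUTPUT_VERTICES:
            raise ValueError(f"unknown output set {self.index!r}")
        if not self.delta > self.gamma:
            raise ValueError("delta must exceed gamma")

    @property
    def vertex(self) -> float:
        return self.gamma + OUTPUT_VERTICES[self.index] * (self.delta - self.gamma)

    def membership(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        half = (self.delta - self.gamma) / 2.0
        return np.maximum(0.0, 1.0 - np.abs(y - self.vertex) / half)


# -------------------------------------------------------------------- rules

@dataclass(frozen=True)
class Atom:
    """One antecedent proposition: feature ``IS`` input set."""

    feature: str
    set_index: str


@dataclass(frozen=True)
class And:
    children: tuple

    def __init__(self, *children):
        object.__setattr__(self, "children", tuple(children))


@dataclass(frozen=True)
class Or:
    children: tuple

    def __init__(self, *children):
        object.__setattr__(self, "children", tuple(children))


@dataclass(frozen=True)
class FuzzyRule:
    """IF <antecedent> THEN FM score IS <consequent> (optionally negated)."""

    antecedent: object          # Atom | And | Or tree
    consequent: str             # S1 | S2 | S3
    negated: bool = False
    weight: float = 1.0

    def __post_init__(self):
        if self.consequent not in OUTPUT_VERTICES:
            raise ValueError(f"unknown consequent {self.consequent!r}")
        if self.weight != 1.0:
            raise ValueError("rule weights are fixed at 1")
        if not self.atoms():
            raise ValueError("antecedent must contain at least one atom")

    def atoms(self) -> list[Atom]:
        out = []

        def walk(node):
            if isinstance(node, Atom):
                out.append(node)
            elif isinstance(node, (And, Or)):
                for c in node.children:
                    walk(c)
            else:
                raise TypeError(f"bad antecedent node {node!r}")

        walk(self.antecedent)
        return out


def fire_rule(rule: FuzzyRule, memberships: dict) -> float:
    """Firing strength of a rule: min over AND nodes, max over OR nodes.

    ``memberships`` maps ``(feature, set_index)`` to a degree in [0, 1].
    """

    def ev(node):
        if isinstance(node, Atom):
            key = (node.feature, node.set_index)
            if key not in memberships:
                raise KeyError(f"no membership supplied for atom "
                               f"{node.feature} IS {node.set_index}")
            return memberships[key]
        if isinstance(node, And):
            return min(ev(c) for c in node.children)
        if isinstance(node, Or):
            return max(ev(c) for c in node.children)
        raise TypeError(f"bad antecedent node {node!r}")

    return float(ev(rule.antecedent))


def implicate(strength: float, consequent: OutputSetSpec, grid: np.ndarray,
              negated: bool = False, negated_mode: str = "complement") -> np.ndarray:
    """Truncate the consequent membership curve at the firing strength.

    A negated consequent ("FM score is NOT S1") implicates onto the
    pointwise complement ``1 - mu_S1`` (``negated_mode='complement'``) or
    onto the union of the remaining output sets (``'union'``).
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("firing strength must lie in [0, 1]")
    if not negated:
        return np.minimum(strength, consequent.membership(grid))
    if negated_mode == "complement":
        return np.minimum(strength, 1.0 - consequent.membership(grid))
    if negated_mode == "union":
        others = [OutputSetSpec(s, consequent.gamma, consequent.delta)
                  for s in OUTPUT_VERTICES if s != consequent.index]
        mu = np.maximum.reduce([o.membership(grid) for o in others])
        return np.minimum(strength, mu)
    raise ValueError(f"unknown negated_mode {negated_mode!r}")


@dataclass
class AggregatedOutput:
    """Aggregated output membership sampled on a uniform y-grid."""

    grid: np.ndarray
    membership: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.membership = np.asarray(self.membership, dtype=float)
        if self.grid.shape != self.membership.shape or self.grid.ndim != 1:
            raise ValueError("grid/membership must be equal-length 1-D arrays")
        if len(self.grid) < 1001:
            raise ValueError("grid resolution must be >= 1001 points")
        if self.membership.min() < -1e-12 or self.membership.max() > 1 + 1e-12:
            raise ValueError("membership out of [0, 1]")


def aggregate(curves) -> AggregatedOutput:
    """Pointwise maximum of the truncated consequent curves."""
    curves = list(curves)
    if not curves:
        raise ValueError("nothing to aggregate")
    grid, first = curves[0]
    mu = np.asarray(first, dtype=float)
    for g, c in curves[1:]:
        if g.shape != grid.shape or not np.array_equal(g, grid):
            raise ValueError("curves are sampled on mismatched grids")
        mu = np.maximum(mu, c)
    return AggregatedOutput(grid=grid, membership=mu)


def defuzzify_centroid(agg: AggregatedOutput) -> float:
    """Center of area of the aggregated set, by trapezoidal integration."""
    area = np.trapezoid(agg.membership, agg.grid)
    if area <= 0.0:
        raise ValueError("cannot defuzzify: no rule fired (zero area)")
    return float(np.trapezoid(agg.grid * agg.membership, agg.grid) / area)


def make_grid(n: int = 2001, gamma: float = 0.0, delta: float = 1.0) -> np.ndarray:
    return np.linspace(gamma, delta, n)


@dataclass
class MamdaniSystem:
    """A complete inference system: input sets per feature, rules, y-grid.

    ``input_sets`` maps ``(feature, set_index)`` to a :class:`FuzzySetSpec`.
    """

    input_sets: dict[tuple[str, str], FuzzySetSpec]
    rules: list[FuzzyRule]
    grid_size: int = 2001
    negated_mode: str = "complement"
    _grid: np.ndarray = field(init=False, repr=False)
    _out: dict[str, OutputSetSpec] = field(init=False, repr=False)
    _norm: tuple[float, float] = field(init=False, repr=False)

    def __post_init__(self):
        self._grid = make_grid(self.grid_size)
        self._out = {s: OutputSetSpec(s) for s in OUTPUT_VERTICES}
        for rule in self.rules:
            for atom in rule.atoms():
                if (atom.feature, atom.set_index) not in self.input_sets:
                    raise ValueError(f"rule references unconfigured atom "
                                     f"{atom.feature} IS {atom.set_index}")
        # normalization anchors: centroids when only S3 / only S1 fire fully
        lo = defuzzify_centroid(AggregatedOutput(
            self._grid, self._out["S3"].membership(self._grid)))
        hi = defuzzify_centroid(AggregatedOutput(
            self._grid, self._out["S1"].membership(self._grid)))
        self._norm = (lo, hi)

    @property
    def grid(self) -> np.ndarray:
        return self._grid

    @property
    def centroid_range(self) -> tuple[float, float]:
        """(c_min, c_max): analytically 1/6 and 5/6 for the default sets."""
        return self._norm

    def memberships(self, features: dict[str, float]) -> dict:
        mu = {}
        for (feat, set_idx), spec in self.input_sets.items():
            if feat not in features:
                raise KeyError(f"feature {feat!r} missing from input vector")
            mu[(feat, set_idx)] = spec.membership(features[feat])
        return mu

    def aggregate_output(self, features: dict[str, float]) -> AggregatedOutput:
        mu = self.memberships(features)
        curves = []
        for rule in self.rules:
            s = fire_rule(rule, mu)
            curves.append((self._grid,
                           implicate(s, self._out[rule.consequent], self._grid,
                                     rule.negated, self.negated_mode)))
        return aggregate(curves)

    def evaluate(self, features: dict[str, float]) -> float:
        """Normalized crisp score in [0, 1]."""
        c = defuzzify_centroid(self.aggregate_output(features))
        return normalize_output(c, *self._norm)


def normalize_output(c: float, c_min: float, c_max: float,
                     tol: float = 1e-9) -> float:
    """Rescale a raw centroid linearly so [c_min, c_max] maps onto [0, 1]."""
    if not c_min < c_max:
        raise ValueError("c_min must be below c_max")
    if c < c_min - tol or c > c_max + tol:
        raise ValueError(f"centroid {c} outside attainable range "
                         f"[{c_min}, {c_max}]")
    return float(np.clip((c - c_min) / (c_max - c_min), 0.0, 1.0))
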