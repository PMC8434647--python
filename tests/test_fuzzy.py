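import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fmca import (AggregatedOutput, And, Atom, FuzzyRule, FuzzySetSpec,
                  Or, OutputSetSpec, aggregate, defuzzify_centroid,
                  fire_rule, implicate, normalize_output)
from fmca.fuzzy import make_grid


class TestInputMemberships:
    def test_full_membership_at_desired_value(self):
        r1 = FuzzySetSpec("R1", 0.0, 60.0)
        assert r1.membership(60.0) == 1.0
        assert r1.membership(0.0) == 0.0

    def test_partial_peaks_at_half_desired(self):
        r2 = FuzzySetSpec("R2", 0.0, 60.0)
        assert r2.membership(30.0) == 1.0
        assert r2.membership(0.0) == 0.0
        assert r2.membership(60.0) == 0.0

    def test_not_performed_is_complement(self):
        r3 = FuzzySetSpec("R3", 0.0, 60.0)
        assert r3.membership(0.0) == 1.0

    def test_out_of_universe_clamps(self):
        r1 = FuzzySetSpec("R1", 0.0, 60.0)
        assert r1.membership(90.0) == 1.0
        assert r1.membership(-5.0) == 0.0

    @settings(derandomize=True, max_examples=200)
    @given(x=st.floats(0, 60), pair=st.sampled_from(
        [("R1", "R3"), ("R4", "R5"), ("R6", "R7")]))
    def test_complement_pairs_sum_to_one(self, x, pair):
        a, b = (FuzzySetSpec(i, 0.0, 60.0) for i in pair)
        assert a.membership(x) + b.membership(x) == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(x=st.floats(-50, 150),
           idx=st.sampled_from(["R1", "R2", "R3", "R4", "R5", "R6", "R7"]))
    def test_membership_in_unit_interval(self, x, idx):
        mu = FuzzySetSpec(idx, 0.0, 60.0).membership(x)
        assert 0.0 <= mu <= 1.0


class TestRuleFiring:
    def test_and_is_min_or_is_max(self):
        mu = {("f", "R1"): 0.3, ("g", "R1"): 0.8}
        assert fire_rule(FuzzyRule(And(Atom("f", "R1"), Atom("g", "R1")), "S1"),
                         mu) == 0.3
        assert fire_rule(FuzzyRule(Or(Atom("f", "R1"), Atom("g", "R1")), "S1"),
                         mu) == 0.8

    def test_single_atom_identity(self):
        assert fire_rule(FuzzyRule(Atom("f", "R2"), "S2"),
                         {("f", "R2"): 0.55}) == 0.55

    def test_missing_atom_named(self):
        rule = FuzzyRule(Atom("f", "R1"), "S1")
        with pytest.raises(KeyError, match="f IS R1"):
            fire_rule(rule, {})

    def test_nonunit_weight_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            FuzzyRule(Atom("f", "R1"), "S1", weight=0.5)


class TestImplicationAggregation:
    def test_zero_strength_is_zero_curve(self):
        grid = make_grid()
        out = implicate(0.0, OutputSetSpec("S2"), grid)
        assert not out.any()

    def test_full_strength_is_consequent(self):
        grid = make_grid()
        s2 = OutputSetSpec("S2")
        np.testing.assert_array_equal(implicate(1.0, s2, grid),
                                      s2.membership(grid))

    def test_clip_matches_pointwise_oracle(self):
        grid = make_grid()
        s2 = OutputSetSpec("S2")
        clipped = implicate(0.4, s2, grid)
        expect = np.minimum(0.4, np.maximum(0, 1 - np.abs(grid - 0.5) / 0.5))
        np.testing.assert_allclose(clipped, expect, atol=1e-12)

    def test_negated_consequent_is_complement(self):
        grid = make_grid()
        s1 = OutputSetSpec("S1")
        np.testing.assert_allclose(implicate(1.0, s1, grid, negated=True),
                                   1.0 - s1.membership(grid), atol=1e-12)

    def test_aggregate_is_pointwise_max(self):
        grid = make_grid()
        c1 = implicate(0.7, OutputSetSpec("S1"), grid)
        c2 = implicate(0.5, OutputSetSpec("S3"), grid)
        agg = aggregate([(grid, c1), (grid, c2)])
        np.testing.assert_array_equal(agg.membership, np.maximum(c1, c2))

    def test_aggregate_identity_and_zero(self):
        grid = make_grid()
        c = implicate(0.6, OutputSetSpec("S2"), grid)
        agg = aggregate([(grid, c), (grid, np.zeros_like(grid))])
        np.testing.assert_array_equal(agg.membership, c)

    def test_mismatched_grids_rejected(self):
        g1, g2 = make_grid(2001), make_grid(3001)
        with pytest.raises(ValueError, match="grid"):
            aggregate([(g1, np.zeros_like(g1)), (g2, np.zeros_like(g2))])


class TestDefuzzification:
    def test_symmetric_aggregate_centroid_half(self):
        grid = make_grid()
        mu = np.maximum(OutputSetSpec("S1").membership(grid),
                        OutputSetSpec("S3").membership(grid))
        c = defuzzify_centroid(AggregatedOutput(grid, mu))
        assert c == pytest.approx(0.5, abs=1e-9)

    def test_right_triangle_centroid(self):
        # S3 alone: triangle (0,1)-(0.5,0); centroid of its area is 1/6
        grid = make_grid()
        mu = OutputSetSpec("S3").membership(grid)
        c = defuzzify_centroid(AggregatedOutput(grid, mu))
        assert c == pytest.approx(1.0 / 6.0, abs=1e-6)

    def test_matches_brute_force_integration(self, rng):
        grid = make_grid()
        fine = np.linspace(0, 1, 1_000_001)
        for _ in range(5):
            strengths = rng.uniform(0, 1, size=3)
            curves, fine_curves = [], []
            for s, idx in zip(strengths, ("S1", "S2", "S3")):
                spec = OutputSetSpec(idx)
                curves.append((grid, implicate(s, spec, grid)))
                fine_curves.append(np.minimum(s, spec.membership(fine)))
            c = defuzzify_centroid(aggregate(curves))
            mu = np.maximum.reduce(fine_curves)
            brute = np.trapezoid(fine * mu, fine) / np.trapezoid(mu, fine)
            assert c == pytest.approx(brute, abs=1e-4)

    def test_no_rule_fired_rejected(self):
        grid = make_grid()
        with pytest.raises(ValueError, match="no rule fired"):
            defuzzify_centroid(AggregatedOutput(grid, np.zeros_like(grid)))


class TestNormalization:
    def test_endpoints_and_midpoint(self):
        lo, hi = 1 / 6, 5 / 6
        assert normalize_output(lo, lo, hi) == 0.0
        assert normalize_output(hi, lo, hi) == 1.0
        assert normalize_output(0.5, lo, hi) == pytest.approx(0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            normalize_output(0.9, 1 / 6, 5 / 6)


class TestSystemProperties:
    def test_grid_doubling_stability(self, testdefs, rng):
        """FM_CA is insensitive to output-grid resolution."""
        from fmca.scoring import make_test_definition
        for tid, td in testdefs.items():
            td2 = make_test_definition(tid)
            td2.grid_size = 4001
            td2.__post_init__()
            betas = td.desired_values
            for _ in range(20):
                fv = {f: rng.uniform(0, betas[f]) for f in td.features}
                assert td.system.evaluate(fv) == pytest.approx(
                    td2.system.evaluate(fv), abs=1e-4)

    def test_centroid_strictly_inside_unit_interval(self, testdefs, rng):
        from fmca.fuzzy import defuzzify_centroid
        td = testdefs["T3"]
        for _ in range(50):
            fv = {f: rng.uniform(0, td.desired_values[f]) for f in td.features}
            agg = td.system.aggregate_output(fv)
            c = defuzzify_centroid(agg)
            assert 0.0 < c < 1.0
            assert 0.0 <= td.system.evaluate(fv) <= 1.0
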