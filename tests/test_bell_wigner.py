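"""Tests for Bell-Wigner inequality checks and attenuation sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bistable.bell_wigner import (
    AttenuationSpec,
    BellWignerAssignment,
    assignment_from_joint,
    attenuate,
    independent_assignment,
    inequality_values,
    max_violation,
    sweep,
)

# A fixed witness joint: mass 0.4 on (-,-,-) and 0.6 on (+,+,+), i.e.
# three perfectly correlated events.  Under composed attenuation with
# k = (0.2, 0.9, 0.05) the first Bell-Wigner inequality evaluates to
# -0.138: a genuine violation from a classically realizable base.
CORRELATED_JOINT = [0.4, 0, 0, 0, 0, 0, 0, 0.6]


def violated_ids(assignment):
    return {r.inequality for r in inequality_values(assignment) if r.violated}


joints = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
    min_size=8, max_size=8,
).filter(lambda w: sum(w) > 1e-6)


class TestAssignmentFromJoint:
    def test_uniform_joint(self):
        a = assignment_from_joint([1 / 8] * 8)
        assert a.p1 == a.p2 == a.p3 == pytest.approx(0.5)
        assert a.p12 == a.p13 == a.p23 == pytest.approx(0.25)

    def test_point_mass_on_all_plus(self):
        a = assignment_from_joint([0] * 7 + [1])
        assert a.p1 == a.p2 == a.p3 == 1.0
        assert a.p12 == a.p13 == a.p23 == 1.0

    def test_independent_product_rule(self):
        a = independent_assignment(0.9)
        assert a.p1 == pytest.approx(0.9, abs=1e-12)
        assert a.p12 == pytest.approx(0.81, abs=1e-12)

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            assignment_from_joint([0.2] * 8)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            assignment_from_joint([-0.1, 0.1] + [0.25] * 4)


class TestInequalityValues:
    def test_independent_half_assignment(self):
        a = independent_assignment(0.5)
        records = {r.inequality: r for r in inequality_values(a)}
        assert records["bell-wigner(1)"].value == pytest.approx(0.25, abs=1e-12)
        assert not any(r.violated for r in records.values())

    def test_explicit_violation(self):
        a = BellWignerAssignment(p1=0.1, p2=0.9, p3=0.9, p12=0.81, p13=0.81, p23=0.81)
        records = {r.inequality: r for r in inequality_values(a)}
        assert records["bell-wigner(1)"].value == pytest.approx(-0.71, abs=1e-12)
        assert records["bell-wigner(1)"].violated

    @settings(derandomize=True)
    @given(joints)
    def test_classical_joints_never_violate(self, weights):
        """Any genuine joint distribution satisfies every condition of
        possible experience."""
        w = np.array(weights) / sum(weights)
        assert not violated_ids(assignment_from_joint(w))


class TestAttenuate:
    base = independent_assignment(0.9)

    def test_identity_at_k_one(self):
        spec = AttenuationSpec(1.0, 1.0, 1.0)
        for scheme in (False, True):
            out = attenuate(self.base, spec, marginals_only=scheme)
            assert out.as_dict() == pytest.approx(self.base.as_dict(), abs=1e-15)

    def test_full_ambivalence_collapses_everything(self):
        out = attenuate(self.base, AttenuationSpec(0.5, 0.5, 0.5))
        assert all(v == pytest.approx(0.5) for v in out.as_dict().values())

    def test_single_inverted_parameter_both_schemes(self):
        spec = AttenuationSpec(k1=0.0, k2=1.0, k3=1.0)
        composed = attenuate(self.base, spec)
        assert composed.p1 == pytest.approx(0.1, abs=1e-12)
        assert composed.p12 == pytest.approx(0.19, abs=1e-12)
        assert composed.p23 == pytest.approx(0.81, abs=1e-12)
        bw1 = {r.inequality: r for r in inequality_values(composed)}["bell-wigner(1)"]
        assert bw1.value == pytest.approx(0.53, abs=1e-12)
        assert not bw1.violated

        literal = attenuate(self.base, spec, marginals_only=True)
        assert literal.p12 == pytest.approx(0.81, abs=1e-12)
        bw1 = {r.inequality: r for r in inequality_values(literal)}["bell-wigner(1)"]
        assert bw1.value == pytest.approx(-0.71, abs=1e-12)
        assert bw1.violated

    def test_composition_order_immaterial(self):
        a = attenuate(self.base, AttenuationSpec(0.3, 0.8, 0.6))
        # composing f_ki after f_kj is symmetric: swap events 1 and 2
        # along with their parameters and the joints must relabel.
        swapped_base = BellWignerAssignment(
            p1=self.base.p2, p2=self.base.p1, p3=self.base.p3,
            p12=self.base.p12, p13=self.base.p23, p23=self.base.p13,
        )
        b = attenuate(swapped_base, AttenuationSpec(0.8, 0.3, 0.6))
        assert a.p12 == pytest.approx(b.p12, abs=1e-12)
        assert a.p13 == pytest.approx(b.p23, abs=1e-12)

    @settings(derandomize=True)
    @given(
        joints,
        st.tuples(*[st.floats(min_value=0, max_value=1, allow_nan=False)] * 3),
    )
    def test_attenuation_preserves_unit_interval(self, weights, ks):
        w = np.array(weights) / sum(weights)
        a = assignment_from_joint(w)
        for scheme in (False, True):
            out = attenuate(a, AttenuationSpec(*ks), marginals_only=scheme)
            assert all(-1e-12 <= v <= 1 + 1e-12 for v in out.as_dict().values())

    def test_violation_witnesses_under_both_schemes(self):
        """Bistable attenuation can push a classical assignment outside
        the Bell-Wigner polytope under either joint-handling scheme."""
        correlated = assignment_from_joint(CORRELATED_JOINT)
        composed = attenuate(correlated, AttenuationSpec(0.2, 0.9, 0.05))
        rec = {r.inequality: r for r in inequality_values(composed)}["bell-wigner(1)"]
        assert rec.value == pytest.approx(-0.138, abs=1e-12)
        assert rec.violated

        literal = attenuate(
            independent_assignment(0.9),
            AttenuationSpec(0.5, 1.0, 1.0),
            marginals_only=True,
        )
        rec = {r.inequality: r for r in inequality_values(literal)}["bell-wigner(1)"]
        assert rec.value == pytest.approx(-0.31, abs=1e-12)
        assert rec.violated


class TestSweep:
    def test_identity_grid_single_row(self):
        table = sweep(independent_assignment(0.9), [1.0], [1.0], [1.0],
                      inequality="bell-wigner(1)")
        assert len(table) == 1
        assert not table["violated"].any()

    def test_full_grid_finds_violations_on_fixture(self):
        grid = np.round(np.arange(0.5, 1.01, 0.1), 10)
        table = sweep(
            independent_assignment(0.9), grid, grid, grid,
            inequality="bell-wigner(1)", marginals_only=True,
        )
        assert len(table) == 216
        assert table["violated"].sum() > 0

    def test_max_violation_query(self):
        grid = np.round(np.arange(0.5, 1.01, 0.1), 10)
        table = sweep(
            independent_assignment(0.9), grid, grid, grid,
            inequality="bell-wigner(1)", marginals_only=True,
        )
        worst = max_violation(table, "bell-wigner(1)")
        assert worst["value"] == table["value"].min()
        # strongest violation: event 1 maximally ambivalent
        assert worst["k1"] == pytest.approx(0.5)

    def test_blocks_ordered_by_k3(self):
        table = sweep(independent_assignment(0.9), [0.5, 1.0], [0.5, 1.0],
                      [1.0, 0.9], inequality="bell-wigner(1)")
        assert list(table["k3"].unique()) == [1.0, 0.9]

    def test_relabeling_symmetry(self):
        """Swapping events 1 and 2 with matching swapped (k1, k2)
        permutes inequality values consistently."""
        a = assignment_from_joint([0.1, 0.05, 0.15, 0.1, 0.2, 0.1, 0.05, 0.25])
        swapped = BellWignerAssignment(
            p1=a.p2, p2=a.p1, p3=a.p3, p12=a.p12, p13=a.p23, p23=a.p13
        )
        out_a = attenuate(a, AttenuationSpec(0.6, 0.9, 0.7))
        out_s = attenuate(swapped, AttenuationSpec(0.9, 0.6, 0.7))
        rec_a = {r.inequality: r.value for r in inequality_values(out_a)}
        rec_s = {r.inequality: r.value for r in inequality_values(out_s)}
        assert rec_a["bell-wigner(1)"] == pytest.approx(rec_s["bell-wigner(2)"], abs=1e-12)
        assert rec_a["bell-wigner(3)"] == pytest.approx(rec_s["bell-wigner(3)"], abs=1e-12)
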