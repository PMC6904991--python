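"""Discrete ESSN semantics: guards, arcs, bindings, firing, validation."""

import pytest
from hypothesis import given, settings, strategies as st

from essn import (
    And,
    ArcExpression,
    ColorClass,
    ColorDomain,
    ESSNNet,
    InSubclass,
    Marking,
    MassActionRate,
    Multiset,
    Not,
    SuccRef,
    Transition,
    Variable,
    VarEq,
    VarNeq,
    VarRef,
    enumerate_bindings,
    evaluate_arc,
    evaluate_guard,
    fire,
    validate_net,
)
from tests.conftest import make_ab_net


class TestColorClass:
    def test_circular_successor_order(self, mye):
        assert mye.successor("L1") == "L2"
        assert mye.successor("Lmax") == "Lmin"  # circular wrap
        assert mye.successor("L1", -1) == "Lmin"
        assert mye.successor("L1", 7) == "L3"

    def test_successor_requires_ordered_class(self):
        cls = ColorClass("C", ("a", "b"))
        with pytest.raises(ValueError, match="not ordered"):
            cls.successor("a")

    def test_subclass_partition_violations_detected(self):
        bad = ColorClass("C", ("a", "b"), subclasses={"S1": ("a",)})
        assert any("not covered" in msg for msg in bad.check())
        overlapping = ColorClass("C", ("a", "b"), subclasses={"S1": ("a", "b"), "S2": ("b",)})
        assert any("more than one subclass" in msg for msg in overlapping.check())


class TestGuards:
    def test_subclass_membership(self, mye):
        vc = {"l": mye}
        assert evaluate_guard(InSubclass("l", "Lmin"), {"l": "Lmin"}, vc)
        assert not evaluate_guard(InSubclass("l", "Lmin"), {"l": "L3"}, vc)
        assert evaluate_guard(Not(InSubclass("l", "Lmin")), {"l": "L3"}, vc)

    def test_variable_comparison(self, mye):
        vc = {"x": mye, "y": mye}
        assert not evaluate_guard(VarNeq("x", "y"), {"x": "L2", "y": "L2"}, vc)
        assert evaluate_guard(VarEq("x", "y"), {"x": "L2", "y": "L2"}, vc)

    def test_unbound_variable_is_named(self, mye):
        with pytest.raises(KeyError, match="x"):
            evaluate_guard(VarEq("x", "y"), {"y": "L2"}, {"x": mye, "y": mye})


class TestArcExpressions:
    def test_variable_tuple(self, mye):
        expr = ArcExpression.tuples((VarRef("l"),))
        assert evaluate_arc(expr, {"l": "L2"}, (mye,)) == {("L2",): 1}

    def test_coefficient(self, mye):
        expr = ArcExpression.tuples((2, VarRef("l")))
        assert evaluate_arc(expr, {"l": "L2"}, (mye,)) == {("L2",): 2}

    def test_successor_follows_level_order(self, mye):
        expr = ArcExpression.tuples((SuccRef("l", 1),))
        assert evaluate_arc(expr, {"l": "L1"}, (mye,)) == {("L2",): 1}

    def test_identical_tuples_merge(self, mye):
        expr = ArcExpression.tuples((VarRef("l"),), (2, VarRef("l")))
        assert evaluate_arc(expr, {"l": "L3"}, (mye,)) == {("L3",): 3}

    def test_negative_coefficient_rejected(self):
        with pytest.raises(ValueError):
            ArcExpression(((-1, ()),))


class TestMultiset:
    def test_comparison_and_arithmetic(self):
        a = Multiset({("x",): 2, ("y",): 1})
        b = Multiset({("x",): 1})
        assert b <= a and not a <= b
        assert (a - b) == {("x",): 1, ("y",): 1}
        assert (a + b) == {("x",): 3, ("y",): 1}


class TestBindingEnumeration:
    def _net_with(self, guard, nvars=1):
        net = ESSNNet()
        net.classes["Mye"] = ColorClass(
            "Mye", ("Lmin", "L1", "L2", "L3", "Lmax"), ordered=True
        )
        names = ["l", "m"][:nvars]
        t = Transition(
            "t",
            "mass_action",
            variables=tuple(Variable(n, "Mye") for n in names),
            guard=guard,
            rate=MassActionRate(1.0),
        )
        net.add_transition(t)
        return net, t

    def test_cardinality_is_class_product_without_guard(self):
        from essn import TRUE

        net, t = self._net_with(TRUE)
        assert len(enumerate_bindings(net, t)) == 5
        net2, t2 = self._net_with(TRUE, nvars=2)
        assert len(enumerate_bindings(net2, t2)) == 25

    def test_guard_filters_bindings(self):
        net, t = self._net_with(Not(InSubclass("l", "Lmin")))
        assert [b["l"] for b in enumerate_bindings(net, t)] == ["L1", "L2", "L3", "Lmax"]

    def test_inequality_guard_on_pair(self):
        net = ESSNNet()
        net.classes["C"] = ColorClass("C", ("a", "b", "c"))
        t = Transition(
            "t",
            "mass_action",
            variables=(Variable("x", "C"), Variable("y", "C")),
            guard=VarNeq("x", "y"),
            rate=MassActionRate(1.0),
        )
        net.add_transition(t)
        assert len(enumerate_bindings(net, t)) == 6  # 3*3 - 3

    def test_order_is_deterministic(self):
        from essn import TRUE

        net, t = self._net_with(TRUE, nvars=2)
        bindings = enumerate_bindings(net, t)
        assert bindings == enumerate_bindings(net, t)
        assert bindings[0] == {"l": "Lmin", "m": "Lmin"}
        assert bindings[1] == {"l": "Lmin", "m": "L1"}


class TestFiring:
    def test_neutral_transfer(self):
        net = make_ab_net(a0=3)
        net.m0[("B", ())] = 0
        t = net.transitions["t"]
        m1 = fire(net, net.m0, t, {})
        assert m1[("A", ())] == 2 and m1[("B", ())] == 1
        # the input marking is unmodified
        assert net.m0[("A", ())] == 3

    def test_colored_damage_step_moves_level_down(self, fig1_net):
        m = Marking({("Teff", ()): 2, ("ODC", ("L2",)): 1})
        t = fig1_net.transitions["TeffKillsODC"]
        m1 = fire(fig1_net, m, t, {"l": "L2"})
        assert m1.get(("ODC", ("L2",)), 0) == 0
        assert m1[("ODC", ("L1",))] == 1
        assert m1[("Teff", ())] == 2  # side condition preserved

    def test_not_enabled_names_deficient_place(self):
        net = make_ab_net(a0=0)
        with pytest.raises(ValueError, match="place A"):
            fire(net, Marking(), net.transitions["t"], {})

    def test_guard_false_instance_rejected(self, fig1_net):
        m = Marking({("Teff", ()): 1, ("ODC", ("Lmin",)): 1})
        with pytest.raises(ValueError, match="guard"):
            fire(fig1_net, m, fig1_net.transitions["TeffKillsODC"], {"l": "Lmin"})

    @given(a0=st.integers(1, 50), b0=st.integers(0, 50))
    @settings(max_examples=25, deadline=None)
    def test_fire_then_reverse_fire_restores_marking(self, a0, b0):
        net = make_ab_net(a0=a0)
        net.m0[("B", ())] = b0
        t = net.transitions["t"]
        m1 = fire(net, net.m0, t, {})
        reverse = ESSNNet(
            classes=net.classes,
            places=net.places,
            transitions=net.transitions,
            arcs_in=net.arcs_out,
            arcs_out=net.arcs_in,
        )
        m2 = fire(reverse, m1, t, {})
        nonzero = lambda m: {k: v for k, v in m.items() if v}
        assert nonzero(m2) == nonzero(net.m0)


class TestValidation:
    def test_fig1_net_is_clean(self, fig1_net):
        assert validate_net(fig1_net) == []

    def test_wrong_arity_arc_reported(self, fig1_net):
        fig1_net = _copy_net(fig1_net)
        fig1_net.arcs_in[("ODC", "TeffDeath")] = ArcExpression.neutral()
        diags = validate_net(fig1_net)
        assert any(d.rule == "arc-arity" and "ODC" in d.element for d in diags)

    def test_undeclared_guard_variable_reported(self):
        net = make_ab_net()
        net.add_transition(
            Transition("bad", "mass_action", guard=VarEq("x", "y"), rate=MassActionRate(1.0))
        )
        diags = validate_net(net)
        assert any(d.rule == "guard-variables" for d in diags)

    def test_wraparound_successor_warns_without_guard(self, mye):
        net = ESSNNet()
        net.classes["Mye"] = mye
        net.add_place("P", ColorDomain(("Mye",)))
        t = Transition(
            "up",
            "mass_action",
            variables=(Variable("l", "Mye"),),
            rate=MassActionRate(1.0),
        )
        net.add_transition(t)
        net.add_arc("P", "up", "in", ArcExpression.tuples((VarRef("l"),)))
        net.add_arc("P", "up", "out", ArcExpression.tuples((SuccRef("l", 1),)))
        diags = validate_net(net)
        assert any(d.severity == "warning" and d.rule == "successor-wraparound" for d in diags)
        assert not any(d.severity == "error" for d in diags)

    def test_overlapping_rate_predicates_rejected_in_strict_mode(self, mye):
        net = ESSNNet()
        net.classes["Mye"] = mye
        rate = MassActionRate(
            0.1,
            cases=(
                (Not(InSubclass("l", "Lmin")), 1.0),
                (InSubclass("l", "L2"), 2.0),  # overlaps the first case
            ),
        )
        net.add_transition(
            Transition("t", "mass_action", variables=(Variable("l", "Mye"),), rate=rate)
        )
        assert validate_net(net, strict_rates=False) == []
        assert any(d.rule == "rate-overlap" for d in validate_net(net, strict_rates=True))


def _copy_net(net):
    import copy

    return copy.deepcopy(net)
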