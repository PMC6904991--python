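"""Fluid semantics: speed laws, vector field, event-driven integration."""

import numpy as np
import pytest

from essn import (
    ArcExpression,
    ESSNNet,
    EventSchedule,
    GeneralRate,
    GeneralRateRegistry,
    Marking,
    MassActionRate,
    SolverOptions,
    Transition,
    default_registry,
    mass_action_speed,
    simulate,
    transition_speed,
    unfold,
    vector_field,
)
from tests.conftest import make_ab_net


def _single_instance(net, name="t"):
    system = unfold(net)
    inst = next(i for i in system.instances if i.transition == name)
    return system, inst


class TestMassActionSpeed:
    def test_unary_decay(self):
        net = make_ab_net(a0=100.0)
        system, inst = _single_instance(net)
        x = system.initial_state()
        assert mass_action_speed(x, inst, 0.1) == pytest.approx(10.0)

    def test_bilinear_product(self):
        net = ESSNNet()
        for p in ("A", "B", "C"):
            net.add_place(p)
        net.add_transition(Transition("t", "mass_action", rate=MassActionRate(2.0)))
        net.add_arc("A", "t", "in", ArcExpression.neutral())
        net.add_arc("B", "t", "in", ArcExpression.neutral())
        net.add_arc("C", "t", "out", ArcExpression.neutral())
        net.m0 = Marking({("A", ()): 3.0, ("B", ()): 4.0})
        system, inst = _single_instance(net)
        assert mass_action_speed(system.initial_state(), inst, 2.0) == pytest.approx(24.0)

    def test_multiplicity_exponent(self):
        net = ESSNNet()
        net.add_place("A")
        net.add_place("B")
        net.add_transition(Transition("t", "mass_action", rate=MassActionRate(1.0)))
        net.add_arc("A", "t", "in", ArcExpression.neutral(2))
        net.add_arc("B", "t", "out", ArcExpression.neutral())
        net.m0 = Marking({("A", ()): 5.0})
        system, inst = _single_instance(net)
        assert mass_action_speed(system.initial_state(), inst, 1.0) == pytest.approx(25.0)

    def test_zero_input_gives_zero(self):
        net = make_ab_net(a0=0.0)
        system, inst = _single_instance(net)
        assert mass_action_speed(np.zeros(2), inst, 5.0) == 0.0


class TestTransitionSpeed:
    def test_mass_action_branch_matches_mass_action_speed(self, ab_net):
        system, inst = _single_instance(ab_net)
        x = system.initial_state()
        got = transition_speed(x, 0.0, inst, system.index, default_registry(), {})
        assert got == pytest.approx(mass_action_speed(x, inst, 0.5))

    def test_michaelis_menten_general_speed(self):
        net = make_ab_net()
        net.transitions["t"] = Transition(
            "t", "general", rate=GeneralRate("michaelis_menten", {"Vmax": 10.0, "K": 5.0})
        )
        net.m0 = Marking({("A", ()): 5.0})
        system, inst = _single_instance(net)
        got = transition_speed(
            system.initial_state(), 0.0, inst, system.index, default_registry(), {}
        )
        assert got == pytest.approx(5.0)  # 10*5/(5+5)

    def test_exhausted_consumed_input_forces_zero(self, ab_net):
        system, inst = _single_instance(ab_net)
        x = np.array([0.0, 3.0])
        assert transition_speed(x, 0.0, inst, system.index, default_registry(), {}) == 0.0

    def test_unregistered_function_names_transition(self):
        net = make_ab_net()
        net.transitions["t"] = Transition("t", "general", rate=GeneralRate("nope", {}))
        system, inst = _single_instance(net)
        with pytest.raises(KeyError, match="'t'"):
            transition_speed(
                system.initial_state(), 0.0, inst, system.index, GeneralRateRegistry(), {}
            )


class TestVectorField:
    def test_simple_transfer(self, ab_net):
        system = unfold(ab_net)
        dx = vector_field(system, np.array([10.0, 0.0]), 0.0)
        assert dx == pytest.approx([-5.0, 5.0])

    def test_token_conserving_net_sums_to_zero(self):
        net = make_ab_net()
        system = unfold(net)
        dx = vector_field(system, np.array([7.0, 3.0]), 0.0)
        assert dx.sum() == pytest.approx(0.0, abs=1e-12)

    def test_matches_finite_difference_of_analytic_decay(self):
        # A -> (removed): x_A(nu) = x0 * exp(-omega*nu)
        net = ESSNNet()
        net.add_place("A")
        net.add_transition(Transition("t", "mass_action", rate=MassActionRate(0.5)))
        net.add_arc("A", "t", "in", ArcExpression.neutral())
        system = unfold(net)
        x0, omega = 10.0, 0.5
        for nu in (0.0, 0.5, 2.0):
            x = np.array([x0 * np.exp(-omega * nu)])
            h = 1e-7
            fd = (x0 * np.exp(-omega * (nu + h)) - x0 * np.exp(-omega * (nu - h))) / (2 * h)
            assert vector_field(system, x, nu)[0] == pytest.approx(fd, abs=1e-6)

    def test_parameter_name_resolution_with_phase_multiplier(self):
        net = make_ab_net(omega="k")
        system = unfold(net, {"k": 0.5})
        sched = EventSchedule(phases=[(0.0, 10.0, {"k": 2.0})])
        dx = vector_field(system, np.array([10.0, 0.0]), 1.0, schedule=sched)
        assert dx[0] == pytest.approx(-10.0)
        dx_after = vector_field(system, np.array([10.0, 0.0]), 20.0, schedule=sched)
        assert dx_after[0] == pytest.approx(-5.0)


class TestSimulate:
    def test_exponential_decay_hits_analytic_value(self):
        net = ESSNNet()
        net.add_place("A")
        net.add_transition(Transition("t", "mass_action", rate=MassActionRate(1.0)))
        net.add_arc("A", "t", "in", ArcExpression.neutral())
        net.m0 = Marking({("A", ()): 1.0})
        traj = simulate(unfold(net), horizon=1.0, options=SolverOptions(grid_dt=0.5))
        assert traj.value("A", 1.0) == pytest.approx(np.exp(-1.0), abs=1e-4)

    def test_impulse_jump_equals_amount(self, ab_net):
        sched = EventSchedule()
        sched.add_impulse(60.0, "A", 1000.0)
        traj = simulate(unfold(ab_net), schedule=sched, horizon=100.0)
        ev = traj.events[0]
        assert ev["after"] - ev["before"] == pytest.approx(1000.0)
        assert traj.value("A", 60.0) == pytest.approx(ev["after"])

    def test_mass_conservation_on_conserving_net(self, ab_net):
        opts = SolverOptions()
        traj = simulate(unfold(ab_net), horizon=50.0, options=opts)
        total = traj.states.sum(axis=1)
        assert np.allclose(total, total[0], rtol=10 * opts.rtol)

    def test_tolerance_halving_converges(self, ab_net):
        coarse = simulate(
            unfold(ab_net), horizon=10.0, options=SolverOptions(rtol=1e-6, atol=1e-9)
        )
        fine = simulate(
            unfold(ab_net), horizon=10.0, options=SolverOptions(rtol=5e-7, atol=5e-10)
        )
        diff = abs(fine.states[-1] - coarse.states[-1]).max()
        assert diff < 1e-6 * max(1.0, abs(coarse.states[-1]).max())

    def test_time_rescaling_of_autonomous_mass_action(self):
        # scaling every rate by alpha compresses time by alpha
        alpha = 2.0
        t1 = simulate(
            unfold(make_ab_net(omega=0.3)), horizon=8.0, options=SolverOptions(grid_dt=0.5)
        )
        t2 = simulate(
            unfold(make_ab_net(omega=0.3 * alpha)),
            horizon=4.0,
            options=SolverOptions(grid_dt=0.25),
        )
        assert t2.value("A", 4.0) == pytest.approx(t1.value("A", 8.0), rel=1e-5)

    def test_negative_horizon_rejected(self, ab_net):
        with pytest.raises(ValueError, match="horizon"):
            simulate(unfold(ab_net), horizon=-1.0)

    def test_time_outside_grid_rejected(self, ab_net):
        traj = simulate(unfold(ab_net), horizon=5.0)
        with pytest.raises(ValueError, match="outside"):
            traj.at(6.0)


class TestEventSchedule:
    def test_overlapping_phases_rejected(self):
        sched = EventSchedule(phases=[(0, 10, {"k": 2.0}), (5, 15, {"k": 3.0})])
        with pytest.raises(ValueError, match="overlapping"):
            sched.validate(20.0)

    def test_impulse_outside_horizon_rejected(self):
        sched = EventSchedule()
        sched.add_impulse(400.0, "EBV", 1000.0)
        with pytest.raises(ValueError, match="outside"):
            sched.validate(365.0)

    def test_multipliers_compose_only_in_interval(self):
        sched = EventSchedule(phases=[(0, 10, {"k": 2.0}), (10, 20, {"k": 4.0})])
        assert sched.multiplier("k", 5.0) == 2.0
        assert sched.multiplier("k", 10.0) == 4.0  # closed-open intervals
        assert sched.multiplier("k", 25.0) == 1.0
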