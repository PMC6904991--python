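import numpy as np
import pytest

from essn import (
    ArcExpression,
    ColorClass,
    ColorDomain,
    ESSNNet,
    Marking,
    MassActionRate,
    Transition,
    default_parameters,
    default_scenario,
    run_scenario,
    unfold,
)
from essn.netio import _fig1_net


@pytest.fixture(scope="session")
def mye():
    return ColorClass(
        "Mye",
        ("Lmin", "L1", "L2", "L3", "Lmax"),
        ordered=True,
        subclasses={e: (e,) for e in ("Lmin", "L1", "L2", "L3", "Lmax")},
    )


@pytest.fixture(scope="session")
def fig1_net():
    return _fig1_net()


def make_ab_net(omega=0.5, a0=10.0):
    """Minimal neutral net A -> B with a mass-action rate."""
    net = ESSNNet(name="ab")
    net.add_place("A")
    net.add_place("B")
    net.add_transition(Transition("t", "mass_action", rate=MassActionRate(omega)))
    net.add_arc("A", "t", "in", ArcExpression.neutral())
    net.add_arc("B", "t", "out", ArcExpression.neutral())
    net.m0 = Marking({("A", ()): a0})
    return net


@pytest.fixture
def ab_net():
    return make_ab_net()


@pytest.fixture(scope="session")
def ms_trajectory():
    """The disease-protocol trajectory on default parameters (shared across
    tests; simulation is deterministic)."""
    traj, system = run_scenario(default_scenario("ms"))
    return traj, system


@pytest.fixture(scope="session")
def healthy_trajectory():
    traj, system = run_scenario(default_scenario("healthy"))
    return traj, system


@pytest.fixture(scope="session")
def rrms_nodac_system():
    params = default_parameters("ms")
    from essn import build_rrms_net

    net = build_rrms_net(params, include_dac=False)
    return unfold(net, params.as_dict())
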