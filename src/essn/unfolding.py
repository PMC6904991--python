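"""Unfolding a colored net into an indexed, uncolored ODE-ready system.

Unfolding assigns one state variable to every (place, color tuple) pair and
materializes one transition instance per legal binding.  Each instance
carries sparse input (I), output (O) and incidence (L = O - I) vectors over
the state index, plus the information needed to evaluate its speed in the
fluid regime.  Instances excluded by their guard are never materialized,
which keeps the derived ODE system minimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np

from .core import (
    ESSNNet,
    GeneralRate,
    Marking,
    MassActionRate,
    Transition,
    enumerate_bindings,
    evaluate_arc,
    validate_net,
)

__all__ = ["StateIndex", "TransitionInstance", "UnfoldedSystem", "unfold", "state_of"]


@dataclass(frozen=True)
class StateIndex:
    """Bijection between (place, color tuple) pairs and integer indices.

    Order is deterministic: places in declaration order, colors in
    lexicographic element order within each place's domain.  A neutral
    place contributes the single pair ``(place, ())``.
    """

    pairs: tuple[tuple[str, tuple[str, ...]], ...]
    _lookup: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "pairs", tuple((p, tuple(c)) for p, c in self.pairs))
        object.__setattr__(self, "_lookup", {pc: i for i, pc in enumerate(self.pairs)})

    def __len__(self) -> int:
        return len(self.pairs)

    def index(self, place: str, color: tuple[str, ...] = ()) -> int:
        key = (place, tuple(color))
        if key not in self._lookup:
            raise KeyError(f"no state variable for place {place!r} color {tuple(color)}")
        return self._lookup[key]

    def labels(self) -> list[str]:
        """Human-readable column labels, e.g. ``ODC[L1]`` or ``Teff``."""
        out = []
        for place, color in self.pairs:
            out.append(place if not color else f"{place}[{','.join(color)}]")
        return out


def state_of(index: StateIndex, place: str, color: tuple[str, ...] = ()) -> int:
    """Integer index of the state variable for ``(place, color)``."""
    return index.index(place, color)


@dataclass
class TransitionInstance:
    """One legal binding of a transition, with its incidence structure.

    ``inputs``/``outputs`` map state-variable index -> multiplicity; the
    incidence is their difference.  ``rate`` is the resolved rate for this
    binding: a number or parameter name for mass-action instances, or the
    :class:`~essn.core.GeneralRate` reference for general instances.
    """

    transition: str
    kind: str
    binding: dict[str, str]
    inputs: dict[int, int]
    outputs: dict[int, int]
    rate: Union[float, str, GeneralRate]
    input_places: tuple[str, ...] = ()

    @property
    def consumed(self) -> dict[int, int]:
        """Inputs with positive net consumption (I > O).

        These are the state variables a firing actually depletes; pure
        side conditions (read arcs) are excluded.  The fluid enabling rule
        forces an instance's speed to zero when any *consumed* input is
        exhausted — side conditions are instead handled by the rate law,
        which vanishes with the population it reads (a mass-action speed
        contains the side condition as a factor; an inhibitory read arc
        like the daclizumab one must not disable its target when empty).
        """
        return {
            i: k - self.outputs.get(i, 0)
            for i, k in self.inputs.items()
            if k > self.outputs.get(i, 0)
        }

    @property
    def incidence(self) -> dict[int, int]:
        out = dict(self.outputs)
        for i, k in self.inputs.items():
            out[i] = out.get(i, 0) - k
        return {i: v for i, v in out.items() if v}

    def dense(self, n: int, which: str = "L") -> np.ndarray:
        """Dense export of I, O or L as a length-``n`` vector."""
        vec = np.zeros(n)
        src = {"I": self.inputs, "O": self.outputs, "L": self.incidence}[which]
        for i, v in src.items():
            vec[i] = v
        return vec

    @property
    def label(self) -> str:
        if not self.binding:
            return self.transition
        inner = ",".join(f"{k}={v}" for k, v in self.binding.items())
        return f"{self.transition}<{inner}>"


@dataclass
class UnfoldedSystem:
    """The uncolored system: state index, transition instances, parameters."""

    net: ESSNNet
    index: StateIndex
    instances: list[TransitionInstance]
    params: dict[str, float] = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.index)

    def initial_state(self, m0: Marking | None = None) -> np.ndarray:
        """Dense state vector from a marking (defaults to the net's m0)."""
        m = self.net.m0 if m0 is None else m0
        x = np.zeros(self.n_states)
        for (place, color), qty in m.items():
            x[self.index.index(place, color)] = qty
        return x

    def export_table(self) -> dict:
        """Plain-data export (state list; instances with I/O/L triples)."""
        return {
            "states": self.index.labels(),
            "instances": [
                {
                    "instance": inst.label,
                    "kind": inst.kind,
                    "I": dict(inst.inputs),
                    "O": dict(inst.outputs),
                    "L": inst.incidence,
                }
                for inst in self.instances
            ],
        }


def unfold(net: ESSNNet, params: Mapping[str, float] | None = None) -> UnfoldedSystem:
    """Translate a colored net into its indexed uncolored system.

    One state variable per (place, color) pair — neutral places contribute
    one — and one :class:`TransitionInstance` per guard-legal binding of
    every transition, with I/O/L computed by arc-expression evaluation.
    Raises :class:`ValueError` if the net fails validation.
    """
    diags = [d for d in validate_net(net) if d.severity == "error"]
    if diags:
        raise ValueError(
            "cannot unfold an invalid net:\n" + "\n".join(str(d) for d in diags)
        )

    pairs = []
    for place, dom in net.places.items():
        for color in dom.colors(net.classes):
            pairs.append((place, color))
    index = StateIndex(tuple(pairs))

    instances: list[TransitionInstance] = []
    for t in net.transitions.values():
        vcs = net.var_classes(t)
        in_places = tuple(net.input_places(t.name))
        for binding in enumerate_bindings(net, t):
            inputs: dict[int, int] = {}
            outputs: dict[int, int] = {}
            for place in in_places:
                ms = evaluate_arc(net.arcs_in[(place, t.name)], binding, net.domain_classes(place))
                for color, k in ms.items():
                    i = index.index(place, color)
                    inputs[i] = inputs.get(i, 0) + k
            for place in net.output_places(t.name):
                ms = evaluate_arc(net.arcs_out[(place, t.name)], binding, net.domain_classes(place))
                for color, k in ms.items():
                    i = index.index(place, color)
                    outputs[i] = outputs.get(i, 0) + k
            if isinstance(t.rate, MassActionRate):
                rate: Union[float, str, GeneralRate] = t.rate.resolve(binding, vcs)
            else:
                rate = t.rate
            instances.append(
                TransitionInstance(
                    transition=t.name,
                    kind=t.kind,
                    binding=dict(binding),
                    inputs=inputs,
                    outputs=outputs,
                    rate=rate,
                    input_places=in_places,
                )
            )

    return UnfoldedSystem(net=net, index=index, instances=instances, params=dict(params or {}))
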