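"""Domain types and discrete semantics of Extended Stochastic Symmetric Nets.

An ESSN is a colored Petri net whose transitions are partitioned into a
mass-action set (rates piecewise-constant over bindings) and a general set
(rates given by arbitrary registered functions of the input marking and
time).  Places carry a *color domain* — a Cartesian product of finite color
classes — and arcs are labelled with expressions mapping a transition
binding to a multiset of colored tokens.

This module implements the net structure itself and its discrete
token-game semantics: guard evaluation, arc-expression evaluation, binding
enumeration and transition firing.  The fluid (ODE) semantics lives in
:mod:`essn.unfolding` and :mod:`essn.dynamics`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

__all__ = [
    "ColorClass",
    "ColorDomain",
    "Variable",
    "Guard",
    "TRUE",
    "FALSE",
    "VarEq",
    "VarNeq",
    "InSubclass",
    "SubclassEq",
    "SubclassNeq",
    "And",
    "Or",
    "Not",
    "Multiset",
    "ArcExpression",
    "VarRef",
    "SuccRef",
    "ConstRef",
    "MassActionRate",
    "GeneralRate",
    "Transition",
    "Marking",
    "ESSNNet",
    "Diagnostic",
    "validate_net",
    "evaluate_guard",
    "evaluate_arc",
    "enumerate_bindings",
    "fire",
]


# ---------------------------------------------------------------------------
# Color classes and domains
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColorClass:
    """A finite, ordered-or-unordered set of token colors.

    Parameters
    ----------
    name : str
        Identifier of the class.
    elements : tuple of str
        The colors, in declaration order.  For an ordered class this order
        defines the circular successor function.
    ordered : bool
        Whether ``successor`` is defined on the class.
    subclasses : mapping of str -> tuple of str, optional
        Named static subclasses.  Must form a partition of ``elements``.
        When omitted, every element is its own singleton subclass named
        after the element itself.
    """

    name: str
    elements: tuple[str, ...]
    ordered: bool = False
    subclasses: Mapping[str, tuple[str, ...]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))
        if self.subclasses is None:
            object.__setattr__(
                self, "subclasses", {e: (e,) for e in self.elements}
            )
        else:
            object.__setattr__(
                self,
                "subclasses",
                {k: tuple(v) for k, v in self.subclasses.items()},
            )

    # -- structural checks (used by validate_net) ---------------------------
    def check(self) -> list[str]:
        problems = []
        if len(set(self.elements)) != len(self.elements):
            problems.append(f"color class {self.name}: duplicate elements")
        seen: set[str] = set()
        for sub, members in self.subclasses.items():
            for m in members:
                if m in seen:
                    problems.append(
                        f"color class {self.name}: element {m} in more than one subclass"
                    )
                if m not in self.elements:
                    problems.append(
                        f"color class {self.name}: subclass {sub} references unknown element {m}"
                    )
                seen.add(m)
        if seen != set(self.elements):
            missing = set(self.elements) - seen
            problems.append(
                f"color class {self.name}: elements not covered by subclasses: {sorted(missing)}"
            )
        return problems

    def index(self, element: str) -> int:
        try:
            return self.elements.index(element)
        except ValueError:
            raise KeyError(f"{element!r} is not an element of class {self.name}") from None

    def successor(self, element: str, k: int = 1) -> str:
        """k-th circular successor (negative ``k`` means predecessor)."""
        if not self.ordered:
            raise ValueError(f"class {self.name} is not ordered; successor undefined")
        i = self.index(element)
        return self.elements[(i + k) % len(self.elements)]

    def subclass_of(self, element: str) -> str:
        for sub, members in self.subclasses.items():
            if element in members:
                return sub
        raise KeyError(f"{element!r} is not an element of class {self.name}")


@dataclass(frozen=True)
class ColorDomain:
    """Cartesian product of color classes; the type of tokens in a place.

    ``factors`` is the flat tuple of class names (a class appearing with
    multiplicity *e* is simply repeated *e* times).  The empty tuple is the
    *neutral* domain: its only color is the empty tuple ``()``.
    """

    factors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))

    @property
    def neutral(self) -> bool:
        return not self.factors

    def colors(self, classes: Mapping[str, ColorClass]) -> list[tuple[str, ...]]:
        """All color tuples of the domain, in lexicographic element order."""
        if self.neutral:
            return [()]
        pools = [classes[c].elements for c in self.factors]
        return [tuple(t) for t in itertools.product(*pools)]


@dataclass(frozen=True)
class Variable:
    """A typed transition variable (e.g. ``l`` of class ``Mye``)."""

    name: str
    class_name: str


# ---------------------------------------------------------------------------
# Guards
# ---------------------------------------------------------------------------


class Guard:
    """Base class for guard expression nodes.

    Guards restrict the legal bindings (instances) of a transition.  Basic
    predicates compare bound colors of a shared class, test static-subclass
    membership, or compare the static subclasses of two bound colors.
    """

    def variables(self) -> set[str]:
        raise NotImplementedError

    def evaluate(self, binding: Mapping[str, str], var_classes: Mapping[str, ColorClass]) -> bool:
        raise NotImplementedError


class _Const(Guard):
    def __init__(self, value: bool):
        self.value = value

    def variables(self) -> set[str]:
        return set()

    def evaluate(self, binding, var_classes) -> bool:
        return self.value

    def __repr__(self) -> str:
        return "TRUE" if self.value else "FALSE"


TRUE = _Const(True)
FALSE = _Const(False)


def _bound(binding: Mapping[str, str], var: str) -> str:
    if var not in binding:
        raise KeyError(f"variable {var!r} is not bound")
    return binding[var]


@dataclass(frozen=True)
class VarEq(Guard):
    x: str
    y: str

    def variables(self):
        return {self.x, self.y}

    def evaluate(self, binding, var_classes):
        return _bound(binding, self.x) == _bound(binding, self.y)


@dataclass(frozen=True)
class VarNeq(Guard):
    x: str
    y: str

    def variables(self):
        return {self.x, self.y}

    def evaluate(self, binding, var_classes):
        return _bound(binding, self.x) != _bound(binding, self.y)


@dataclass(frozen=True)
class InSubclass(Guard):
    """``x ∈ C_{i,j}`` — the color bound to ``x`` lies in a static subclass."""

    var: str
    subclass: str

    def variables(self):
        return {self.var}

    def evaluate(self, binding, var_classes):
        cls = var_classes[self.var]
        if self.subclass not in cls.subclasses:
            raise KeyError(f"class {cls.name} has no subclass {self.subclass!r}")
        return _bound(binding, self.var) in cls.subclasses[self.subclass]


@dataclass(frozen=True)
class SubclassEq(Guard):
    """``d(x) = d(y)`` — the bound colors share a static subclass."""

    x: str
    y: str

    def variables(self):
        return {self.x, self.y}

    def evaluate(self, binding, var_classes):
        cx = var_classes[self.x].subclass_of(_bound(binding, self.x))
        cy = var_classes[self.y].subclass_of(_bound(binding, self.y))
        return cx == cy


@dataclass(frozen=True)
class SubclassNeq(Guard):
    x: str
    y: str

    def variables(self):
        return {self.x, self.y}

    def evaluate(self, binding, var_classes):
        return not SubclassEq(self.x, self.y).evaluate(binding, var_classes)


class And(Guard):
    def __init__(self, *terms: Guard):
        self.terms = terms

    def variables(self):
        return set().union(*(t.variables() for t in self.terms)) if self.terms else set()

    def evaluate(self, binding, var_classes):
        return all(t.evaluate(binding, var_classes) for t in self.terms)

    def __repr__(self):
        return "And(%s)" % ", ".join(map(repr, self.terms))


class Or(Guard):
    def __init__(self, *terms: Guard):
        self.terms = terms

    def variables(self):
        return set().union(*(t.variables() for t in self.terms)) if self.terms else set()

    def evaluate(self, binding, var_classes):
        return any(t.evaluate(binding, var_classes) for t in self.terms)

    def __repr__(self):
        return "Or(%s)" % ", ".join(map(repr, self.terms))


class Not(Guard):
    def __init__(self, term: Guard):
        self.term = term

    def variables(self):
        return self.term.variables()

    def evaluate(self, binding, var_classes):
        return not self.term.evaluate(binding, var_classes)

    def __repr__(self):
        return f"Not({self.term!r})"


def evaluate_guard(
    guard: Guard,
    binding: Mapping[str, str],
    var_classes: Mapping[str, ColorClass],
) -> bool:
    """Evaluate a guard under a binding.

    ``var_classes`` maps each transition variable to its :class:`ColorClass`
    (needed to resolve static-subclass predicates).  Raises :class:`KeyError`
    naming the variable if the binding leaves a guard variable unbound.
    """
    return guard.evaluate(binding, var_classes)


# ---------------------------------------------------------------------------
# Multisets and arc expressions
# ---------------------------------------------------------------------------


class Multiset(dict):
    """Multiset of color tuples: mapping tuple -> nonnegative multiplicity.

    Zero-multiplicity keys are dropped on construction; arithmetic keeps the
    invariant multiplicity >= 0 only for ``-`` when the left operand covers
    the right (use ``<=`` to check first).
    """

    def __init__(self, items: Mapping[tuple, int] | Iterable[tuple[tuple, int]] = ()):
        super().__init__()
        it = items.items() if isinstance(items, Mapping) else items
        for key, mult in it:
            if mult < 0:
                raise ValueError(f"negative multiplicity {mult} for {key}")
            if mult:
                self[tuple(key)] = self.get(tuple(key), 0) + mult

    def __le__(self, other: "Multiset") -> bool:
        return all(other.get(k, 0) >= v for k, v in self.items())

    def __add__(self, other: "Multiset") -> "Multiset":
        out = Multiset(self)
        for k, v in other.items():
            out[k] = out.get(k, 0) + v
        return out

    def __sub__(self, other: "Multiset") -> "Multiset":
        out = Multiset(self)
        for k, v in other.items():
            new = out.get(k, 0) - v
            if new < 0:
                raise ValueError(f"multiset subtraction would go negative at {k}")
            if new:
                out[k] = new
            else:
                out.pop(k, None)
        return out


# Arc-expression tuple components --------------------------------------------


@dataclass(frozen=True)
class VarRef:
    """A declared transition variable appearing in a tuple position."""

    name: str


@dataclass(frozen=True)
class SuccRef:
    """``succ^k`` of a variable of an ordered class (k<0 means predecessor)."""

    name: str
    k: int = 1


@dataclass(frozen=True)
class ConstRef:
    """A constant color element."""

    color: str


Component = Union[VarRef, SuccRef, ConstRef]


@dataclass(frozen=True)
class ArcExpression:
    """Linear combination of color tuples with nonnegative integer coefficients.

    ``terms`` is a tuple of ``(coefficient, component-tuple)`` pairs.  For a
    neutral place the component tuple is empty and the expression reduces to
    a plain arc multiplicity.
    """

    terms: tuple[tuple[int, tuple[Component, ...]], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "terms", tuple((int(c), tuple(t)) for c, t in self.terms)
        )
        for c, _ in self.terms:
            if c < 0:
                raise ValueError("arc coefficients must be nonnegative")

    @classmethod
    def neutral(cls, weight: int = 1) -> "ArcExpression":
        return cls(((weight, ()),))

    @classmethod
    def tuples(cls, *terms) -> "ArcExpression":
        """Convenience: ``tuples((2, VarRef('l')), (1, ConstRef('Lmax')))``.

        Each argument is either a component tuple (coefficient 1) or a
        ``(coefficient, *components)`` tuple whose first element is an int.
        """
        out = []
        for term in terms:
            if term and isinstance(term[0], int):
                out.append((term[0], tuple(term[1:])))
            else:
                out.append((1, tuple(term)))
        return cls(tuple(out))

    def variables(self) -> set[str]:
        out: set[str] = set()
        for _, comps in self.terms:
            for comp in comps:
                if isinstance(comp, (VarRef, SuccRef)):
                    out.add(comp.name)
        return out


def evaluate_arc(
    expr: ArcExpression,
    binding: Mapping[str, str],
    domain_classes: Sequence[ColorClass],
) -> Multiset:
    """Evaluate an arc expression under a binding into a :class:`Multiset`.

    ``domain_classes`` are the classes of the place's color domain, one per
    tuple position; successor components require the class at that position
    to be ordered (circular successor in the declared element order).
    Coefficients of identical resulting tuples are summed.
    """
    acc: dict[tuple[str, ...], int] = {}
    for coef, comps in expr.terms:
        if len(comps) != len(domain_classes):
            raise ValueError(
                f"arc tuple arity {len(comps)} does not match place domain arity {len(domain_classes)}"
            )
        color = []
        for comp, cls in zip(comps, domain_classes):
            if isinstance(comp, VarRef):
                color.append(_bound(binding, comp.name))
            elif isinstance(comp, SuccRef):
                color.append(cls.successor(_bound(binding, comp.name), comp.k))
            else:
                color.append(comp.color)
        key = tuple(color)
        acc[key] = acc.get(key, 0) + coef
    return Multiset(acc)


# ---------------------------------------------------------------------------
# Rates and transitions
# ---------------------------------------------------------------------------

RateValue = Union[float, str]  # a number, or the name of a model parameter


@dataclass(frozen=True)
class MassActionRate:
    """Piecewise-constant rate for a mass-action transition.

    ``cases`` is an ordered list of (guard-like predicate, rate) pairs; the
    first predicate matching the binding wins, ``default`` applies when none
    matches.  Rates may be numbers or parameter names resolved at
    simulation time.  The classical formulation requires the predicates to
    be mutually exclusive; first-match semantics is a superset of that and
    a strict validation mode rejects overlapping predicates.
    """

    default: RateValue
    cases: tuple[tuple[Guard, RateValue], ...] = ()

    def resolve(self, binding, var_classes) -> RateValue:
        for pred, rate in self.cases:
            if pred.evaluate(binding, var_classes):
                return rate
        return self.default


@dataclass(frozen=True)
class GeneralRate:
    """Reference to a registered general rate function plus named parameters.

    Parameter values may be numbers or names of model parameters (resolved
    against the unfolded system's parameter map at simulation time).
    """

    fn_id: str
    params: Mapping[str, RateValue] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "params", dict(self.params))


@dataclass(frozen=True)
class Transition:
    """A colored transition: variables, guard and rate specification.

    ``kind`` is ``"mass_action"`` (speed = rate constant times the product of
    input abundances raised to their arc multiplicities) or ``"general"``
    (speed given by a registered function of the input marking and time).
    """

    name: str
    kind: str  # "mass_action" | "general"
    variables: tuple[Variable, ...] = ()
    guard: Guard = TRUE
    rate: Union[MassActionRate, GeneralRate] = MassActionRate(0.0)

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        if self.kind not in ("mass_action", "general"):
            raise ValueError(f"unknown transition kind {self.kind!r}")


# ---------------------------------------------------------------------------
# Markings
# ---------------------------------------------------------------------------


class Marking(dict):
    """State of the net: mapping ``(place, color tuple) -> quantity``.

    Quantities are nonnegative integers under the discrete token game and
    nonnegative reals in the fluid regime.  Absent keys mean zero.
    """

    def __init__(self, items: Mapping = ()):
        super().__init__()
        it = items.items() if isinstance(items, Mapping) else items
        for (place, color), qty in it:
            if qty < 0:
                raise ValueError(f"negative marking for {place}{tuple(color)}")
            if qty:
                self[(place, tuple(color))] = qty

    def place_multiset(self, place: str) -> Multiset:
        return Multiset({c: int(q) for (p, c), q in self.items() if p == place})

    def copy(self) -> "Marking":
        out = Marking()
        dict.update(out, self)
        return out


# ---------------------------------------------------------------------------
# The net
# ---------------------------------------------------------------------------


@dataclass
class Diagnostic:
    """A validation finding: severity ``error`` or ``warning``."""

    severity: str
    element: str
    rule: str
    message: str

    def __str__(self) -> str:
        return f"[{self.severity}] {self.element}: {self.message} ({self.rule})"


@dataclass
class ESSNNet:
    """An Extended Stochastic Symmetric Net.

    Fields mirror the formal tuple: color classes, places with their color
    domains, transitions (mass-action and general), input/output arc
    expressions indexed by ``(place, transition)``, and the initial marking.
    """

    classes: dict[str, ColorClass] = field(default_factory=dict)
    places: dict[str, ColorDomain] = field(default_factory=dict)
    transitions: dict[str, Transition] = field(default_factory=dict)
    arcs_in: dict[tuple[str, str], ArcExpression] = field(default_factory=dict)
    arcs_out: dict[tuple[str, str], ArcExpression] = field(default_factory=dict)
    m0: Marking = field(default_factory=Marking)
    name: str = "net"

    # -- structural helpers --------------------------------------------------
    def var_classes(self, t: Transition) -> dict[str, ColorClass]:
        return {v.name: self.classes[v.class_name] for v in t.variables}

    def domain_classes(self, place: str) -> tuple[ColorClass, ...]:
        return tuple(self.classes[c] for c in self.places[place].factors)

    def input_places(self, t: str) -> list[str]:
        return [p for (p, tt) in self.arcs_in if tt == t]

    def output_places(self, t: str) -> list[str]:
        return [p for (p, tt) in self.arcs_out if tt == t]

    def add_place(self, name: str, domain: ColorDomain | None = None) -> None:
        self.places[name] = domain or ColorDomain()

    def add_transition(self, t: Transition) -> None:
        self.transitions[t.name] = t

    def add_arc(self, place: str, transition: str, direction: str, expr: ArcExpression) -> None:
        if direction == "in":
            self.arcs_in[(place, transition)] = expr
        elif direction == "out":
            self.arcs_out[(place, transition)] = expr
        else:
            raise ValueError(f"direction must be 'in' or 'out', got {direction!r}")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def validate_net(net: ESSNNet, strict_rates: bool = False) -> list[Diagnostic]:
    """Check the structural well-formedness of a net.

    Returns a (possibly empty) list of :class:`Diagnostic`; ``error``
    severity marks a violated invariant, ``warning`` marks suspicious but
    legal constructs (currently: successor/predecessor arcs whose owning
    transition's guard does not exclude the circular wrap-around at the
    class boundary).  With ``strict_rates`` the piecewise mass-action rate
    predicates must be mutually exclusive over the legal bindings.
    """
    out: list[Diagnostic] = []

    def err(element: str, rule: str, message: str) -> None:
        out.append(Diagnostic("error", element, rule, message))

    def warn(element: str, rule: str, message: str) -> None:
        out.append(Diagnostic("warning", element, rule, message))

    for cls in net.classes.values():
        for msg in cls.check():
            err(cls.name, "color-class", msg)

    for pname, dom in net.places.items():
        for c in dom.factors:
            if c not in net.classes:
                err(pname, "place-domain", f"unknown color class {c!r}")

    for tname, t in net.transitions.items():
        for v in t.variables:
            if v.class_name not in net.classes:
                err(tname, "variable-class", f"variable {v.name} has unknown class {v.class_name!r}")
        declared = {v.name for v in t.variables}
        undeclared = t.guard.variables() - declared
        if undeclared:
            err(tname, "guard-variables", f"guard references undeclared variables {sorted(undeclared)}")
        if t.kind == "general" and not isinstance(t.rate, GeneralRate):
            err(tname, "rate-kind", "general transition requires a GeneralRate")
        if t.kind == "mass_action" and not isinstance(t.rate, MassActionRate):
            err(tname, "rate-kind", "mass-action transition requires a MassActionRate")

    for (pname, tname), expr in itertools.chain(net.arcs_in.items(), net.arcs_out.items()):
        label = f"arc {pname}<->{tname}"
        if pname not in net.places:
            err(label, "arc-place", f"unknown place {pname!r}")
            continue
        if tname not in net.transitions:
            err(label, "arc-transition", f"unknown transition {tname!r}")
            continue
        t = net.transitions[tname]
        declared = {v.name for v in t.variables}
        undeclared = expr.variables() - declared
        if undeclared:
            err(label, "arc-variables", f"references undeclared variables {sorted(undeclared)}")
            continue
        dom = net.places[pname]
        var_class = {v.name: v.class_name for v in t.variables}
        for _, comps in expr.terms:
            if len(comps) != len(dom.factors):
                err(
                    label,
                    "arc-arity",
                    f"tuple arity {len(comps)} does not match domain arity {len(dom.factors)} of place {pname}",
                )
                continue
            for pos, (comp, cls_name) in enumerate(zip(comps, dom.factors)):
                cls = net.classes.get(cls_name)
                if cls is None:
                    continue
                if isinstance(comp, VarRef):
                    if var_class.get(comp.name) != cls_name:
                        err(label, "arc-typing", f"variable {comp.name} (class {var_class.get(comp.name)}) in position {pos} of class {cls_name}")
                elif isinstance(comp, SuccRef):
                    if var_class.get(comp.name) != cls_name:
                        err(label, "arc-typing", f"variable {comp.name} in position {pos} of class {cls_name}")
                    elif not cls.ordered:
                        err(label, "arc-successor", f"successor on unordered class {cls_name}")
                    else:
                        _check_wraparound(net, t, comp, cls, label, warn)
                elif isinstance(comp, ConstRef):
                    if comp.color not in cls.elements:
                        err(label, "arc-typing", f"constant {comp.color!r} is not in class {cls_name}")

    for (pname, color), qty in net.m0.items():
        if pname not in net.places:
            err(f"m0[{pname}]", "marking-place", f"unknown place {pname!r}")
            continue
        dom = net.places[pname]
        legal = len(color) == len(dom.factors) and all(
            c in net.classes.get(cn, ColorClass(cn, ())).elements
            for c, cn in zip(color, dom.factors)
        )
        if not legal:
            err(f"m0[{pname}]", "marking-color", f"color {color} not in cd({pname})")

    if strict_rates:
        for tname, t in net.transitions.items():
            if isinstance(t.rate, MassActionRate) and len(t.rate.cases) > 1:
                vcs = net.var_classes(t)
                for b in enumerate_bindings(net, t):
                    hits = [i for i, (pred, _) in enumerate(t.rate.cases) if pred.evaluate(b, vcs)]
                    if len(hits) > 1:
                        err(tname, "rate-overlap", f"rate predicates {hits} overlap on binding {b}")
                        break
    return out


def _check_wraparound(net, t, comp: SuccRef, cls: ColorClass, label: str, warn) -> None:
    """Warn when succ/pred can wrap circularly under some legal binding."""
    n = len(cls.elements)
    if n == 0 or comp.k % n == 0:
        return
    for b in enumerate_bindings(net, t):
        i = cls.index(b[comp.name])
        if not (0 <= i + comp.k < n):
            warn(
                label,
                "successor-wraparound",
                f"succ^{comp.k}({comp.name}) wraps around class {cls.name} for binding {b}; "
                "guards usually exclude the boundary element",
            )
            return


def enumerate_bindings(net: ESSNNet, t: Transition) -> list[dict[str, str]]:
    """All legal bindings of a transition, in deterministic order.

    The Cartesian product of each variable's class elements (variables in
    declaration order, elements in class order), filtered by the guard.
    """
    vcs = net.var_classes(t)
    names = [v.name for v in t.variables]
    pools = [net.classes[v.class_name].elements for v in t.variables]
    out = []
    for combo in itertools.product(*pools):
        b = dict(zip(names, combo))
        if evaluate_guard(t.guard, b, vcs):
            out.append(b)
    return out


def _arc_multiset(net: ESSNNet, arcs, place: str, t: Transition, binding) -> Multiset:
    expr = arcs.get((place, t.name))
    if expr is None:
        return Multiset()
    return evaluate_arc(expr, binding, net.domain_classes(place))


def fire(net: ESSNNet, m: Marking, t: Transition, binding: Mapping[str, str]) -> Marking:
    """Fire an enabled transition instance; returns the successor marking.

    The instance must be enabled: its guard holds under ``binding`` and each
    input place contains at least the multiset the input arc withdraws
    (multiset comparison).  The input marking is left unmodified.
    """
    vcs = net.var_classes(t)
    if not evaluate_guard(t.guard, binding, vcs):
        raise ValueError(f"instance <{t.name},{binding}> is not enabled: guard is false")
    new = m.copy()
    for place in net.input_places(t.name):
        need = _arc_multiset(net, net.arcs_in, place, t, binding)
        have = m.place_multiset(place)
        if not need <= have:
            deficient = next(c for c, k in need.items() if have.get(c, 0) < k)
            raise ValueError(
                f"instance <{t.name},{binding}> not enabled: place {place} color {deficient} "
                f"has {have.get(deficient, 0)} < {need[deficient]}"
            )
        for color, k in need.items():
            key = (place, color)
            left = new.get(key, 0) - k
            if left:
                new[key] = left
            else:
                new.pop(key, None)
    for place in net.output_places(t.name):
        add = _arc_multiset(net, net.arcs_out, place, t, binding)
        for color, k in add.items():
            key = (place, color)
            new[key] = new.get(key, 0) + k
    return new
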