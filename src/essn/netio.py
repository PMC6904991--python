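"""Net documents, ODE rendering and programmatic fixtures.

A *net document* is the package's canonical structured-text dialect for an
ESSN: a YAML document with a schema version header and sections for color
classes, places, transitions, arcs and the initial marking.  Guards and
arc expressions are embedded as compact strings with the grammar

    guard  :=  or_expr
    or     :=  and_expr ("or" and_expr)*
    and    :=  not_expr ("and" not_expr)*
    not    :=  "not" not_expr | "(" or ")" | atom
    atom   :=  "true" | "false" | x "=" y | x "!=" y | x "in" SUB
             | "d(" x ")" ("="|"!=") "d(" y ")"

    arc    :=  INT                      (neutral place)
             | term ("+" term)*         (colored place)
    term   :=  [INT] "<" comp ("," comp)* ">"
    comp   :=  VAR | "succ(" VAR ")" | "pred(" VAR ")"
             | "succ^" INT "(" VAR ")" | CONST-COLOR

An identifier in a tuple position is a variable if the owning transition
declares it, otherwise a constant color.  ``parse_net`` and ``render_net``
round-trip: rendering is canonical, so ``render(parse(render(parse(d))))
== render(parse(d))``.
"""

from __future__ import annotations

import re
from typing import Mapping

import numpy as np
import yaml

from .core import (
    And,
    ArcExpression,
    ColorClass,
    ColorDomain,
    ConstRef,
    ESSNNet,
    FALSE,
    GeneralRate,
    Guard,
    InSubclass,
    Marking,
    MassActionRate,
    Not,
    Or,
    SubclassEq,
    SubclassNeq,
    SuccRef,
    Transition,
    TRUE,
    Variable,
    VarEq,
    VarNeq,
    VarRef,
    _Const,
    validate_net,
)
from .unfolding import UnfoldedSystem

__all__ = [
    "NetSyntaxError",
    "NetSemanticError",
    "parse_net",
    "render_net",
    "parse_guard",
    "render_guard",
    "parse_arc_expression",
    "render_arc_expression",
    "render_odes",
    "make_fixtures",
]

SCHEMA_VERSION = 1


class NetSyntaxError(ValueError):
    """Malformed document or embedded expression."""


class NetSemanticError(ValueError):
    """Well-formed document that does not describe a valid net."""


# ---------------------------------------------------------------------------
# Guard strings
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*(\(|\)|!=|=|,|d\(|[A-Za-z_][A-Za-z_0-9]*|\S)")


def _tokenize(text: str) -> list[str]:
    out, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            break
        out.append(m.group(1))
        pos = m.end()
    return out


def parse_guard(text: str) -> Guard:
    """Parse a guard string (see module grammar)."""
    toks = _tokenize(text)
    pos = 0

    def peek():
        return toks[pos] if pos < len(toks) else None

    def take(expected=None):
        nonlocal pos
        if pos >= len(toks):
            raise NetSyntaxError(f"guard {text!r}: unexpected end of input")
        tok = toks[pos]
        if expected is not None and tok != expected:
            raise NetSyntaxError(f"guard {text!r}: expected {expected!r}, got {tok!r}")
        pos += 1
        return tok

    def atom() -> Guard:
        tok = peek()
        if tok == "(":
            take()
            g = or_expr()
            take(")")
            return g
        if tok == "not":
            take()
            return Not(atom())
        if tok == "true":
            take()
            return TRUE
        if tok == "false":
            take()
            return FALSE
        if tok == "d(":
            take()
            x = take()
            take(")")
            op = take()
            if op not in ("=", "!="):
                raise NetSyntaxError(f"guard {text!r}: expected = or != after d({x})")
            take("d(")
            y = take()
            take(")")
            return SubclassEq(x, y) if op == "=" else SubclassNeq(x, y)
        x = take()
        op = take()
        if op == "in":
            sub = take()
            return InSubclass(x, sub)
        if op == "=":
            return VarEq(x, take())
        if op == "!=":
            return VarNeq(x, take())
        raise NetSyntaxError(f"guard {text!r}: unexpected operator {op!r}")

    def and_expr() -> Guard:
        terms = [atom()]
        while peek() == "and":
            take()
            terms.append(atom())
        return terms[0] if len(terms) == 1 else And(*terms)

    def or_expr() -> Guard:
        terms = [and_expr()]
        while peek() == "or":
            take()
            terms.append(and_expr())
        return terms[0] if len(terms) == 1 else Or(*terms)

    g = or_expr()
    if pos != len(toks):
        raise NetSyntaxError(f"guard {text!r}: trailing tokens {toks[pos:]}")
    return g


def render_guard(g: Guard) -> str:
    if isinstance(g, _Const):
        return "true" if g.value else "false"
    if isinstance(g, VarEq):
        return f"{g.x} = {g.y}"
    if isinstance(g, VarNeq):
        return f"{g.x} != {g.y}"
    if isinstance(g, InSubclass):
        return f"{g.var} in {g.subclass}"
    if isinstance(g, SubclassEq):
        return f"d({g.x}) = d({g.y})"
    if isinstance(g, SubclassNeq):
        return f"d({g.x}) != d({g.y})"
    if isinstance(g, Not):
        return f"not ({render_guard(g.term)})"
    if isinstance(g, And):
        return " and ".join(f"({render_guard(t)})" for t in g.terms) if g.terms else "true"
    if isinstance(g, Or):
        return " or ".join(f"({render_guard(t)})" for t in g.terms) if g.terms else "false"
    raise TypeError(f"cannot render guard node {g!r}")


# ---------------------------------------------------------------------------
# Arc-expression strings
# ---------------------------------------------------------------------------

_TERM = re.compile(r"\s*(?:(\d+)\s*\*?\s*)?<([^>]*)>\s*")
_SUCC = re.compile(r"(succ|pred)(?:\^(-?\d+))?\(\s*([A-Za-z_][A-Za-z_0-9]*)\s*\)$")


def parse_arc_expression(text: str, variables: Mapping[str, str]) -> ArcExpression:
    """Parse an arc-expression string.

    ``variables`` maps the owning transition's variable names to their
    classes; an identifier in a tuple position is a variable reference if
    declared there, a constant color otherwise.
    """
    text = text.strip()
    if re.fullmatch(r"\d+", text):
        return ArcExpression.neutral(int(text))
    terms = []
    for part in text.split("+"):
        m = _TERM.fullmatch(part)
        if not m:
            raise NetSyntaxError(f"bad arc term {part.strip()!r} in {text!r}")
        coef = int(m.group(1)) if m.group(1) else 1
        comps = []
        inner = m.group(2).strip()
        if inner:
            for comp in inner.split(","):
                comp = comp.strip()
                sm = _SUCC.fullmatch(comp)
                if sm:
                    k = int(sm.group(2)) if sm.group(2) else 1
                    if sm.group(1) == "pred":
                        k = -k
                    comps.append(SuccRef(sm.group(3), k))
                elif comp in variables:
                    comps.append(VarRef(comp))
                else:
                    comps.append(ConstRef(comp))
        terms.append((coef, tuple(comps)))
    return ArcExpression(tuple(terms))


def render_arc_expression(expr: ArcExpression) -> str:
    if len(expr.terms) == 1 and not expr.terms[0][1]:
        return str(expr.terms[0][0])
    parts = []
    for coef, comps in expr.terms:
        inner = []
        for c in comps:
            if isinstance(c, VarRef):
                inner.append(c.name)
            elif isinstance(c, SuccRef):
                fn = "succ" if c.k > 0 else "pred"
                k = abs(c.k)
                inner.append(f"{fn}({c.name})" if k == 1 else f"{fn}^{k}({c.name})")
            else:
                inner.append(c.color)
        body = f"<{','.join(inner)}>"
        parts.append(body if coef == 1 else f"{coef}{body}")
    return " + ".join(parts)


# ---------------------------------------------------------------------------
# Net documents
# ---------------------------------------------------------------------------


def parse_net(document: str) -> ESSNNet:
    """Parse a net document into an :class:`ESSNNet`.

    Raises :class:`NetSyntaxError` on malformed YAML or expression strings
    and :class:`NetSemanticError` (naming the offending element) when the
    parsed net fails validation.
    """
    try:
        doc = yaml.safe_load(document)
    except yaml.YAMLError as exc:
        raise NetSyntaxError(f"invalid YAML: {exc}") from exc
    if not isinstance(doc, dict) or "essn" not in doc:
        raise NetSyntaxError("not a net document: missing 'essn' schema version header")
    if doc["essn"] != SCHEMA_VERSION:
        raise NetSyntaxError(f"unsupported schema version {doc['essn']!r}")

    net = ESSNNet(name=doc.get("name", "net"))
    for cname, spec in (doc.get("classes") or {}).items():
        net.classes[cname] = ColorClass(
            cname,
            tuple(spec["elements"]),
            ordered=bool(spec.get("ordered", False)),
            subclasses={k: tuple(v) for k, v in spec["subclasses"].items()}
            if spec.get("subclasses")
            else None,
        )
    for pname, factors in (doc.get("places") or {}).items():
        for f in factors or ():
            if f not in net.classes:
                raise NetSemanticError(f"place {pname!r} references unknown class {f!r}")
        net.add_place(pname, ColorDomain(tuple(factors or ())))

    var_maps: dict[str, dict[str, str]] = {}
    for tname, spec in (doc.get("transitions") or {}).items():
        variables = tuple(
            Variable(v, c) for v, c in (spec.get("variables") or {}).items()
        )
        for v in variables:
            if v.class_name not in net.classes:
                raise NetSemanticError(
                    f"transition {tname!r}: variable {v.name!r} has unknown class {v.class_name!r}"
                )
        var_maps[tname] = {v.name: v.class_name for v in variables}
        guard = parse_guard(spec["guard"]) if spec.get("guard") else TRUE
        kind = spec.get("kind", "mass_action")
        rspec = spec.get("rate") or {}
        if kind == "general":
            rate = GeneralRate(rspec["fn"], rspec.get("params") or {})
        else:
            cases = tuple(
                (parse_guard(g), r) for g, r in (rspec.get("cases") or ())
            )
            rate = MassActionRate(rspec.get("default", 0.0), cases)
        net.add_transition(Transition(tname, kind, variables, guard, rate))

    for arc in doc.get("arcs") or ():
        place, tname, direction, expr_text = arc
        if tname not in net.transitions:
            raise NetSemanticError(f"arc references unknown transition {tname!r}")
        if place not in net.places:
            raise NetSemanticError(f"arc references unknown place {place!r}")
        expr = parse_arc_expression(str(expr_text), var_maps[tname])
        net.add_arc(place, tname, direction, expr)

    for key, qty in (doc.get("marking") or {}).items():
        if "[" in key:
            pname, rest = key.split("[", 1)
            color = tuple(s.strip() for s in rest.rstrip("]").split(","))
        else:
            pname, color = key, ()
        net.m0[(pname, color)] = qty

    errors = [d for d in validate_net(net) if d.severity == "error"]
    if errors:
        raise NetSemanticError("; ".join(str(d) for d in errors))
    return net


def render_net(net: ESSNNet) -> str:
    """Render a net to its canonical document form."""
    doc: dict = {"essn": SCHEMA_VERSION, "name": net.name}
    if net.classes:
        doc["classes"] = {
            c.name: {
                "elements": list(c.elements),
                "ordered": c.ordered,
                "subclasses": {k: list(v) for k, v in c.subclasses.items()},
            }
            for c in net.classes.values()
        }
    doc["places"] = {p: list(d.factors) for p, d in net.places.items()}
    transitions = {}
    for t in net.transitions.values():
        spec: dict = {"kind": t.kind}
        if t.variables:
            spec["variables"] = {v.name: v.class_name for v in t.variables}
        g = render_guard(t.guard)
        if g != "true":
            spec["guard"] = g
        if isinstance(t.rate, GeneralRate):
            spec["rate"] = {"fn": t.rate.fn_id, "params": dict(t.rate.params)}
        else:
            rspec: dict = {"default": t.rate.default}
            if t.rate.cases:
                rspec["cases"] = [[render_guard(g), r] for g, r in t.rate.cases]
            spec["rate"] = rspec
        transitions[t.name] = spec
    doc["transitions"] = transitions
    arcs = []
    for (p, tn), expr in net.arcs_in.items():
        arcs.append([p, tn, "in", render_arc_expression(expr)])
    for (p, tn), expr in net.arcs_out.items():
        arcs.append([p, tn, "out", render_arc_expression(expr)])
    doc["arcs"] = arcs
    if net.m0:
        doc["marking"] = {
            (f"{p}[{','.join(c)}]" if c else p): q for (p, c), q in net.m0.items()
        }
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=None)


# ---------------------------------------------------------------------------
# Human-readable ODE rendering
# ---------------------------------------------------------------------------


def _state_symbol(label: str) -> str:
    return "x_" + re.sub(r"[^A-Za-z0-9_]", "_", label).strip("_")


def render_odes(unfolded: UnfoldedSystem) -> str:
    """One human-readable equation per state variable.

    Mass-action terms are expanded (rate constant times input powers);
    general terms appear as function calls named by their registered
    identifier with the instance binding.  State symbols are sanitized to
    be parseable by symbolic tools (``ODC[L1]`` becomes ``x_ODC_L1``).
    """
    labels = unfolded.index.labels()
    syms = [_state_symbol(lab) for lab in labels]
    terms: dict[int, list[str]] = {i: [] for i in range(len(syms))}
    for inst in unfolded.instances:
        if inst.kind == "mass_action":
            rate = inst.rate
            factors = [str(rate) if not isinstance(rate, str) else rate]
            for idx, mult in inst.inputs.items():
                factors.append(syms[idx] if mult == 1 else f"{syms[idx]}**{mult}")
            speed = "*".join(factors)
        else:
            args = ", ".join(
                syms[i]
                for i in sorted(inst.inputs)
            )
            name = inst.rate.fn_id
            if inst.binding:
                name += "_" + "_".join(v for v in inst.binding.values())
            speed = f"{name}({args}, nu)" if args else f"{name}(nu)"
        for idx, l in inst.incidence.items():
            if l == 1:
                terms[idx].append(f"+ {speed}")
            elif l == -1:
                terms[idx].append(f"- {speed}")
            elif l > 0:
                terms[idx].append(f"+ {l}*{speed}")
            else:
                terms[idx].append(f"- {abs(l)}*{speed}")
    lines = [f"# ODE system for net {unfolded.net.name!r}: {len(syms)} equations"]
    for i, sym in enumerate(syms):
        rhs = " ".join(terms[i]) if terms[i] else "0"
        lines.append(f"d{sym}/dnu = {rhs}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def _fig1_net() -> ESSNNet:
    """The effector/oligodendrocyte toy subnet: a neutral Teff place and an
    ODC place colored by the five-level Mye class, with effector death,
    per-level myelin damage (general kinetics) and remyelination."""
    from .rrms import MYE_LEVELS  # local import to avoid a cycle

    net = ESSNNet(name="fig1")
    net.classes["Mye"] = ColorClass(
        "Mye", MYE_LEVELS, ordered=True, subclasses={e: (e,) for e in MYE_LEVELS}
    )
    net.add_place("Teff")
    net.add_place("ODC", ColorDomain(("Mye",)))
    net.add_transition(
        Transition("TeffDeath", "mass_action", rate=MassActionRate(0.15))
    )
    net.add_arc("Teff", "TeffDeath", "in", ArcExpression.neutral())
    l_var = (Variable("l", "Mye"),)
    net.add_transition(
        Transition(
            "TeffKillsODC",
            "general",
            variables=l_var,
            guard=Not(InSubclass("l", "Lmin")),
            rate=GeneralRate("teff_kills_odc", {"r": 0.01, "K_Teff": 200.0}),
        )
    )
    net.add_arc("Teff", "TeffKillsODC", "in", ArcExpression.neutral())
    net.add_arc("ODC", "TeffKillsODC", "in", ArcExpression.tuples((VarRef("l"),)))
    net.add_arc("Teff", "TeffKillsODC", "out", ArcExpression.neutral())
    net.add_arc("ODC", "TeffKillsODC", "out", ArcExpression.tuples((SuccRef("l", -1),)))
    net.add_transition(
        Transition(
            "Remyelinization",
            "mass_action",
            variables=l_var,
            guard=And(Not(InSubclass("l", "Lmin")), Not(InSubclass("l", "Lmax"))),
            rate=MassActionRate(0.005),
        )
    )
    net.add_arc("ODC", "Remyelinization", "in", ArcExpression.tuples((VarRef("l"),)))
    net.add_arc("ODC", "Remyelinization", "out", ArcExpression.tuples((SuccRef("l", 1),)))
    net.m0[("Teff", ())] = 10
    net.m0[("ODC", ("Lmax",))] = 500
    return net


def _random_ma_net(n: int, rng: np.random.Generator, conserving: bool) -> ESSNNet:
    net = ESSNNet(name=f"random_ma_{n}")
    places = [f"P{i}" for i in range(n)]
    for p in places:
        net.add_place(p)
        net.m0[(p, ())] = int(rng.integers(1, 20))
    # a chain keeps the net connected; extra random transitions densify it
    edges = [(i, (i + 1) % n) for i in range(n - 1)]
    extra = int(rng.integers(1, n + 1))
    for _ in range(extra):
        i, j = rng.choice(n, size=2, replace=False)
        edges.append((int(i), int(j)))
    for k, (i, j) in enumerate(edges):
        name = f"t{k}"
        rate = round(float(rng.uniform(0.05, 1.0)), 4)
        net.add_transition(Transition(name, "mass_action", rate=MassActionRate(rate)))
        net.add_arc(places[i], name, "in", ArcExpression.neutral())
        if conserving:
            net.add_arc(places[j], name, "out", ArcExpression.neutral())
        else:
            w = int(rng.integers(1, 3))
            net.add_arc(places[j], name, "out", ArcExpression.neutral(w))
    return net


def make_fixtures(kind: str, seed: int = 0, n: int = 5) -> str:
    """Programmatic fixture documents.

    ``fig1``: the effector/oligodendrocyte toy subnet.  ``random_ma``: a
    connected random mass-action net with ``n`` neutral places.
    ``random_ma_conserving``: same but every transition has one input and
    one output arc of weight 1 (token-conserving).  Reproducible by seed.
    """
    if kind == "fig1":
        return render_net(_fig1_net())
    if kind in ("random_ma", "random_ma_conserving"):
        rng = np.random.default_rng(seed)
        return render_net(_random_ma_net(n, rng, kind == "random_ma_conserving"))
    raise KeyError(f"unknown fixture kind {kind!r}")
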