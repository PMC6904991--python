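"""The Relapsing-Remitting Multiple Sclerosis (RRMS) reference model.

An immune-system ESSN with seven modules — regulatory T cells (Treg),
effector T cells (Teff), Epstein-Barr virus (EBV), natural killer cells
(NK), interleukin-2 (IL2), oligodendrocytes (ODC) and daclizumab (DAC) —
over 10 places and 22 transitions.  The ODC place is colored by the
ordered class ``Mye`` with five myelination levels ``Lmin < L1 < L2 < L3
< Lmax``; effector attack moves an ODC one level toward ``Lmin``
(irreversible demyelination, excluded from remyelination by guard) and
remyelination moves it one level up.

The model mechanism: EBV injections activate resting effector T cells via
molecular mimicry; activated Teff clear the virus but also attack the
myelin sheath of ODCs.  Regulatory T cells and NK cells suppress the
self-reactive effectors; IL2 fuels the proliferation of all three cell
types; memory effectors give a faster secondary response.  Daclizumab
inhibits IL2-driven duplication of Treg and Teff.

Exact rate constants of the original study are not published in the main
text; the packaged ``healthy`` and ``ms`` parameter sets are this
package's own calibration (see ``config/rrms_defaults.yaml`` and the
methods note) and every value can be overridden by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .core import (
    And,
    ArcExpression,
    ColorClass,
    ColorDomain,
    ConstRef,
    ESSNNet,
    GeneralRate,
    InSubclass,
    Marking,
    MassActionRate,
    Not,
    SuccRef,
    Transition,
    Variable,
    VarRef,
)
from .dynamics import (
    EventSchedule,
    GeneralRateRegistry,
    SolverOptions,
    Trajectory,
    simulate,
)
from .sensitivity import ParameterSpace
from .unfolding import UnfoldedSystem, unfold

__all__ = [
    "MYE_LEVELS",
    "RRMSParameters",
    "ScenarioSpec",
    "rrms_registry",
    "build_rrms_net",
    "default_parameters",
    "default_scenario",
    "default_parameter_space",
    "run_scenario",
    "pct_irreversible_odc",
    "ebv_clearance_times",
]

MYE_LEVELS = ("Lmin", "L1", "L2", "L3", "Lmax")

# The nine rate constants swept in the calibration workflow.
CALIBRATION_PARAMETERS = (
    "TeffKillsODC",
    "TregKillsTeff",
    "TeffKillsEBV",
    "Remyelinization",
    "TregDup",
    "TeffDup",
    "NKdup",
    "TeffActivation",
    "TregActivation",
)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RRMSParameters:
    """One nonnegative rate constant per transition plus kinetic shape
    parameters.

    Rates are per day; populations are counts per reference volume (cells
    or particles per mm^3).  ``p_eff_dup`` is the probability that an
    effector duplication is symmetric (two Teff); the complementary
    ``p_eff_mem`` produces one Teff and one effector-memory cell.
    ``resting_teff_setpoint``/``resting_treg_setpoint`` are the thymic
    output set-points the ``FromTimo*`` transitions replenish toward.
    """

    # thymic replenishment
    FromTimoREG: float = 0.1
    FromTimoEFF: float = 0.1
    resting_treg_setpoint: float = 63.0
    resting_teff_setpoint: float = 1687.0
    # Treg module
    TregActivation: float = 0.5
    TregDeath: float = 0.1
    TregKillsTeff: float = 0.001
    TregDup: float = 0.3
    # Teff module
    TeffActivation: float = 0.01
    TeffDeath: float = 0.15
    TeffDup: float = 1.2
    p_eff_dup: float = 0.6
    TeffKillsEBV: float = 0.01
    TeffKillsODC: float = 0.266
    MemActivation: float = 0.3
    # EBV module (continuous rate zero: injections are impulse events)
    EBVinj: float = 0.0
    # NK module
    NKentry: float = 18.75
    NKDeath: float = 0.05
    NKKillsTeff: float = 0.001
    NKKillsTreg: float = 0.0005
    NKdup: float = 1.3e-4
    # ODC module
    Remyelinization: float = 0.005
    # DAC module
    DACinj: float = 0.0
    DACDegradation: float = 0.0768  # ln(100)/60: 99% degraded in 60 days
    # kinetic shape parameters (saturation constants)
    K_EBV: float = 500.0
    K_Teff: float = 500.0
    K_Treg: float = 100.0
    K_IL2: float = 300.0
    K_DAC: float = 20.0
    il2_per_activation: float = 25.0

    @property
    def p_eff_mem(self) -> float:
        return 1.0 - self.p_eff_dup

    def __post_init__(self):
        if not 0.0 <= self.p_eff_dup <= 1.0:
            raise ValueError(f"p_eff_dup must be in [0,1], got {self.p_eff_dup}")
        for name, value in self.as_dict().items():
            if name.startswith(("K_", "p_", "resting", "il2")):
                continue
            if value < 0:
                raise ValueError(f"rate constant {name} must be >= 0, got {value}")

    def as_dict(self) -> dict[str, float]:
        out = {f: getattr(self, f) for f in self.__dataclass_fields__}
        out["p_eff_mem"] = self.p_eff_mem
        return out

    def with_overrides(self, **overrides: float) -> "RRMSParameters":
        return replace(self, **overrides)


def default_parameters(label: str = "ms") -> RRMSParameters:
    """The packaged calibrated parameter set for ``"healthy"`` or ``"ms"``.

    These are the package's own calibration of the unpublished rate
    constants: the ``ms`` set reproduces the disease regime (progressive
    irreversible ODC damage under repeated EBV exposure), the ``healthy``
    set the protective regime (virus cleared, minimal damage).
    """
    text = resources.files("essn").joinpath("config/rrms_defaults.yaml").read_text()
    doc = yaml.safe_load(text)
    if label not in doc:
        raise KeyError(f"unknown parameter set {label!r}; have {sorted(doc)}")
    values = dict(doc.get("shared", {}))
    values.update(doc[label])
    return RRMSParameters(**values)


# ---------------------------------------------------------------------------
# General rate functions (the model's non-mass-action kinetics)
# ---------------------------------------------------------------------------


def _neutral(xhat: Mapping, place: str, default: float = 0.0) -> float:
    return xhat.get((place, ()), default)


def rrms_registry() -> GeneralRateRegistry:
    """Registry with the RRMS model's general kinetics.

    All forms are saturating (Michaelis-Menten-like) laws; the exact
    functional forms used in the original study are unpublished, so these
    are the package's documented stand-ins with configurable saturation
    constants.
    """
    reg = GeneralRateRegistry()

    def replenish(pool_place: str):
        # thymic output keeps the resting pool at its set-point
        def fn(xhat, nu, params, binding):
            return params["k"] * max(0.0, params["setpoint"] - _neutral(xhat, pool_place))

        return fn

    reg.register("replenish_resting_treg", replenish("Resting_Treg"))
    reg.register("replenish_resting_teff", replenish("Resting_Teff"))

    def treg_activation(xhat, nu, params, binding):
        # resting Treg activated in response to effector expansion and virus
        pool = _neutral(xhat, "Resting_Treg")
        teff = _neutral(xhat, "Teff")
        ebv = _neutral(xhat, "EBV")
        return (
            params["r"]
            * pool
            * (teff / (params["K_Teff"] + teff))
            * (ebv / (params["K_EBV"] + ebv))
        )

    reg.register("treg_activation", treg_activation)

    def teff_activation(xhat, nu, params, binding):
        pool = _neutral(xhat, "Resting_Teff")
        ebv = _neutral(xhat, "EBV")
        return params["r"] * pool * ebv / (params["K_EBV"] + ebv)

    reg.register("teff_activation", teff_activation)

    def mem_activation(xhat, nu, params, binding):
        mem = _neutral(xhat, "EffectorMemory")
        ebv = _neutral(xhat, "EBV")
        return params["r"] * mem * ebv / (params["K_EBV"] + ebv)

    reg.register("mem_activation", mem_activation)

    def kill(pred_place: str, prey_place: str, k_name: str):
        # predator-prey contact saturating in the prey abundance
        def fn(xhat, nu, params, binding):
            pred = _neutral(xhat, pred_place)
            prey = _neutral(xhat, prey_place)
            return params["r"] * pred * prey / (params[k_name] + prey)

        return fn

    reg.register("treg_kills_teff", kill("Treg", "Teff", "K_Teff"))
    reg.register("nk_kills_teff", kill("NK", "Teff", "K_Teff"))
    reg.register("nk_kills_treg", kill("NK", "Treg", "K_Treg"))

    def teff_kills_odc(xhat, nu, params, binding):
        # per-level demyelination: saturating in the effector abundance
        teff = _neutral(xhat, "Teff")
        odc = xhat.get(("ODC", (binding["l"],)), 0.0)
        return params["r"] * odc * teff / (params["K_Teff"] + teff)

    reg.register("teff_kills_odc", teff_kills_odc)

    def dup(cell_place: str):
        # IL2-fuelled duplication, inhibited by daclizumab when present
        def fn(xhat, nu, params, binding):
            cell = _neutral(xhat, cell_place)
            il2 = _neutral(xhat, "IL2")
            dac = _neutral(xhat, "DAC")
            inhibition = 1.0 / (1.0 + dac / params["K_DAC"]) if dac > 0 else 1.0
            return (
                params["r"]
                * params.get("p", 1.0)
                * cell
                * il2
                / (params["K_IL2"] + il2)
                * inhibition
            )

        return fn

    reg.register("treg_dup", dup("Treg"))
    reg.register("teff_dup", dup("Teff"))
    return reg


# ---------------------------------------------------------------------------
# Net construction
# ---------------------------------------------------------------------------


def _t(place: str, mult: int = 1) -> ArcExpression:
    """Neutral-place arc with the given multiplicity."""
    return ArcExpression.neutral(mult)


def build_rrms_net(
    params: RRMSParameters | None = None, include_dac: bool = True
) -> ESSNNet:
    """Construct the RRMS ESSN (10 places / 22 transitions with DAC;
    9 places / 20 transitions without).

    ``ODC`` is colored by the ordered class ``Mye`` (Lmin..Lmax, singleton
    static subclasses); all other places are neutral.  Mass-action rate
    specifications reference parameter names, resolved at simulation time
    against the parameter map, so phase schedules (e.g. pregnancy) can
    rescale them.
    """
    params = params or default_parameters("ms")
    net = ESSNNet(name="rrms" if include_dac else "rrms_nodac")
    net.classes["Mye"] = ColorClass(
        "Mye", MYE_LEVELS, ordered=True, subclasses={e: (e,) for e in MYE_LEVELS}
    )

    for p in (
        "Resting_Treg",
        "Treg",
        "Resting_Teff",
        "Teff",
        "EffectorMemory",
        "EBV",
        "NK",
        "IL2",
    ):
        net.add_place(p)
    net.add_place("ODC", ColorDomain(("Mye",)))
    if include_dac:
        net.add_place("DAC")

    def ma(name: str, rate) -> None:
        net.add_transition(Transition(name, "mass_action", rate=MassActionRate(rate)))

    def general(name: str, fn_id: str, fn_params: Mapping, variables=(), guard=None) -> None:
        net.add_transition(
            Transition(
                name,
                "general",
                variables=variables,
                guard=guard if guard is not None else And(),
                rate=GeneralRate(fn_id, fn_params),
            )
        )

    # --- Treg module -------------------------------------------------------
    general(
        "FromTimoREG",
        "replenish_resting_treg",
        {"k": "FromTimoREG", "setpoint": "resting_treg_setpoint"},
    )
    net.add_arc("Resting_Treg", "FromTimoREG", "in", _t("Resting_Treg"))
    net.add_arc("Resting_Treg", "FromTimoREG", "out", _t("Resting_Treg", 2))

    general(
        "TregActivation",
        "treg_activation",
        {"r": "TregActivation", "K_Teff": "K_Teff", "K_EBV": "K_EBV"},
    )
    for p in ("Resting_Treg", "Teff", "EBV"):
        net.add_arc(p, "TregActivation", "in", _t(p))
    for p in ("Treg", "Teff", "EBV"):
        net.add_arc(p, "TregActivation", "out", _t(p))

    ma("TregDeath", "TregDeath")
    net.add_arc("Treg", "TregDeath", "in", _t("Treg"))

    general("TregKillsTeff", "treg_kills_teff", {"r": "TregKillsTeff", "K_Teff": "K_Teff"})
    net.add_arc("Treg", "TregKillsTeff", "in", _t("Treg"))
    net.add_arc("Teff", "TregKillsTeff", "in", _t("Teff"))
    net.add_arc("Treg", "TregKillsTeff", "out", _t("Treg"))

    general("TregDup", "treg_dup", {"r": "TregDup", "K_IL2": "K_IL2", "K_DAC": "K_DAC"})
    net.add_arc("Treg", "TregDup", "in", _t("Treg"))
    net.add_arc("IL2", "TregDup", "in", _t("IL2"))
    net.add_arc("Treg", "TregDup", "out", _t("Treg", 2))

    # --- Teff module -------------------------------------------------------
    general(
        "FromTimoEFF",
        "replenish_resting_teff",
        {"k": "FromTimoEFF", "setpoint": "resting_teff_setpoint"},
    )
    net.add_arc("Resting_Teff", "FromTimoEFF", "in", _t("Resting_Teff"))
    net.add_arc("Resting_Teff", "FromTimoEFF", "out", _t("Resting_Teff", 2))

    general("TeffActivation", "teff_activation", {"r": "TeffActivation", "K_EBV": "K_EBV"})
    net.add_arc("Resting_Teff", "TeffActivation", "in", _t("Resting_Teff"))
    net.add_arc("EBV", "TeffActivation", "in", _t("EBV"))
    net.add_arc("Teff", "TeffActivation", "out", _t("Teff"))
    net.add_arc("EBV", "TeffActivation", "out", _t("EBV"))
    # each activation event releases a burst of IL2 molecules
    net.add_arc("IL2", "TeffActivation", "out", _t("IL2", max(1, int(round(params.il2_per_activation)))))

    ma("TeffDeath", "TeffDeath")
    net.add_arc("Teff", "TeffDeath", "in", _t("Teff"))

    general(
        "TeffDup_Sym",
        "teff_dup",
        {"r": "TeffDup", "p": "p_eff_dup", "K_IL2": "K_IL2", "K_DAC": "K_DAC"},
    )
    net.add_arc("Teff", "TeffDup_Sym", "in", _t("Teff"))
    net.add_arc("IL2", "TeffDup_Sym", "in", _t("IL2"))
    net.add_arc("Teff", "TeffDup_Sym", "out", _t("Teff", 2))

    general(
        "TeffDup_Asym",
        "teff_dup",
        {"r": "TeffDup", "p": "p_eff_mem", "K_IL2": "K_IL2", "K_DAC": "K_DAC"},
    )
    net.add_arc("Teff", "TeffDup_Asym", "in", _t("Teff"))
    net.add_arc("IL2", "TeffDup_Asym", "in", _t("IL2"))
    net.add_arc("Teff", "TeffDup_Asym", "out", _t("Teff"))
    net.add_arc("EffectorMemory", "TeffDup_Asym", "out", _t("EffectorMemory"))

    ma("TeffKillsEBV", "TeffKillsEBV")
    net.add_arc("Teff", "TeffKillsEBV", "in", _t("Teff"))
    net.add_arc("EBV", "TeffKillsEBV", "in", _t("EBV"))
    net.add_arc("Teff", "TeffKillsEBV", "out", _t("Teff"))

    l_var = (Variable("l", "Mye"),)
    general(
        "TeffKillsODC",
        "teff_kills_odc",
        {"r": "TeffKillsODC", "K_Teff": "K_Teff"},
        variables=l_var,
        guard=Not(InSubclass("l", "Lmin")),
    )
    net.add_arc("Teff", "TeffKillsODC", "in", _t("Teff"))
    net.add_arc("ODC", "TeffKillsODC", "in", ArcExpression.tuples((VarRef("l"),)))
    net.add_arc("Teff", "TeffKillsODC", "out", _t("Teff"))
    net.add_arc("ODC", "TeffKillsODC", "out", ArcExpression.tuples((SuccRef("l", -1),)))

    general("MemActivation", "mem_activation", {"r": "MemActivation", "K_EBV": "K_EBV"})
    net.add_arc("EffectorMemory", "MemActivation", "in", _t("EffectorMemory"))
    net.add_arc("EBV", "MemActivation", "in", _t("EBV"))
    net.add_arc("Teff", "MemActivation", "out", _t("Teff"))
    net.add_arc("EBV", "MemActivation", "out", _t("EBV"))

    # --- EBV module --------------------------------------------------------
    # Injections are impulse events; the transition documents the inflow.
    ma("EBVinj", "EBVinj")
    net.add_arc("EBV", "EBVinj", "out", _t("EBV"))

    # --- NK module ---------------------------------------------------------
    ma("NKentry", "NKentry")
    net.add_arc("NK", "NKentry", "out", _t("NK"))

    ma("NKDeath", "NKDeath")
    net.add_arc("NK", "NKDeath", "in", _t("NK"))

    general("NKKillsTeff", "nk_kills_teff", {"r": "NKKillsTeff", "K_Teff": "K_Teff"})
    net.add_arc("NK", "NKKillsTeff", "in", _t("NK"))
    net.add_arc("Teff", "NKKillsTeff", "in", _t("Teff"))
    net.add_arc("NK", "NKKillsTeff", "out", _t("NK"))

    general("NKKillsTreg", "nk_kills_treg", {"r": "NKKillsTreg", "K_Treg": "K_Treg"})
    net.add_arc("NK", "NKKillsTreg", "in", _t("NK"))
    net.add_arc("Treg", "NKKillsTreg", "in", _t("Treg"))
    net.add_arc("NK", "NKKillsTreg", "out", _t("NK"))

    ma("NKdup", "NKdup")
    net.add_arc("NK", "NKdup", "in", _t("NK"))
    net.add_arc("IL2", "NKdup", "in", _t("IL2"))
    net.add_arc("NK", "NKdup", "out", _t("NK", 2))

    # --- ODC module --------------------------------------------------------
    # Remyelination moves one level up; irreversibly damaged (Lmin) and
    # fully myelinated (Lmax) cells are excluded by guard.
    net.add_transition(
        Transition(
            "Remyelinization",
            "mass_action",
            variables=l_var,
            guard=And(Not(InSubclass("l", "Lmin")), Not(InSubclass("l", "Lmax"))),
            rate=MassActionRate("Remyelinization"),
        )
    )
    net.add_arc("ODC", "Remyelinization", "in", ArcExpression.tuples((VarRef("l"),)))
    net.add_arc("ODC", "Remyelinization", "out", ArcExpression.tuples((SuccRef("l", 1),)))

    # --- DAC module --------------------------------------------------------
    if include_dac:
        ma("DACinj", "DACinj")
        net.add_arc("DAC", "DACinj", "out", _t("DAC"))
        ma("DACDegradation", "DACDegradation")
        net.add_arc("DAC", "DACDegradation", "in", _t("DAC"))
        # daclizumab inhibits the IL2-driven duplications: the DAC place is
        # a side condition read by their rate functions
        for t in ("TregDup", "TeffDup_Sym", "TeffDup_Asym"):
            net.add_arc("DAC", t, "in", _t("DAC"))
            net.add_arc("DAC", t, "out", _t("DAC"))

    return net


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


def _standard_marking() -> Marking:
    return Marking(
        {
            ("ODC", ("Lmax",)): 500,
            ("Resting_Teff", ()): 1687,
            ("Resting_Treg", ()): 63,
            ("NK", ()): 375,
            ("IL2", ()): 1000,
        }
    )


@dataclass
class ScenarioSpec:
    """A simulation protocol: initial marking, dosing schedules, horizon.

    ``label`` selects the parameter-set default (``healthy`` uses the
    protective calibration, the others the disease calibration).  EBV
    injections and the DAC dose are impulse events; pregnancy trimesters
    are piecewise multiplicative phases on the activation rate constants,
    compounding per trimester and resetting at delivery.
    """

    label: str = "ms"
    initial_marking: Marking = field(default_factory=_standard_marking)
    ebv_times: tuple[float, ...] = (0.0, 60.0, 120.0, 180.0, 240.0)
    ebv_amount: float = 1000.0
    dac_time: float | None = None
    dac_dose: float = 300.0
    dac_degradation_days: float = 60.0  # time to ~99% degradation, in [30, 90]
    pregnancy_start: float | None = None
    trimester_multiplier: float = 1.0
    delivery_day: float = 273.0  # relative to pregnancy start
    horizon: float = 365.0
    include_dac: bool | None = None
    param_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for t in self.ebv_times:
            if not 0 <= t <= self.horizon:
                raise ValueError(f"EBV injection at {t} outside [0, {self.horizon}]")
        if self.dac_time is not None and not 0 <= self.dac_time <= self.horizon:
            raise ValueError(f"DAC dose at {self.dac_time} outside [0, {self.horizon}]")
        if self.trimester_multiplier <= 0:
            raise ValueError("trimester multiplier must be > 0")

    @property
    def uses_dac(self) -> bool:
        # the reference protocols run on the full net; the DAC place stays
        # at zero (inert) unless a dose is scheduled
        if self.include_dac is not None:
            return self.include_dac
        return True

    def schedule(self) -> EventSchedule:
        sched = EventSchedule()
        for t in self.ebv_times:
            sched.add_impulse(t, "EBV", self.ebv_amount)
        if self.dac_time is not None:
            sched.add_impulse(self.dac_time, "DAC", self.dac_dose)
        if self.pregnancy_start is not None and self.trimester_multiplier != 1.0:
            m = self.trimester_multiplier
            start = self.pregnancy_start
            tri = self.delivery_day / 3.0
            for i in range(3):
                t0 = start + i * tri
                t1 = min(start + (i + 1) * tri, self.horizon)
                if t0 >= self.horizon:
                    break
                factor = m ** (i + 1)  # compounding per trimester
                sched.add_phase(
                    t0, t1, {"TregActivation": factor, "TeffActivation": 1.0 / factor}
                )
        return sched

    def to_yaml(self) -> str:
        doc = {
            "label": self.label,
            "horizon": self.horizon,
            "initial_marking": {
                f"{p}[{','.join(c)}]" if c else p: float(q)
                for (p, c), q in self.initial_marking.items()
            },
            "ebv": {"times": list(self.ebv_times), "amount": self.ebv_amount},
            "dac": {
                "time": self.dac_time,
                "dose": self.dac_dose,
                "degradation_days": self.dac_degradation_days,
            },
            "pregnancy": {
                "start": self.pregnancy_start,
                "trimester_multiplier": self.trimester_multiplier,
                "delivery_day": self.delivery_day,
            },
            "param_overrides": dict(self.param_overrides),
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioSpec":
        doc = yaml.safe_load(text)
        marking = Marking()
        for key, q in doc.get("initial_marking", {}).items():
            if "[" in key:
                place, rest = key.split("[", 1)
                color = tuple(rest.rstrip("]").split(","))
            else:
                place, color = key, ()
            marking[(place, color)] = q
        kwargs = dict(
            label=doc.get("label", "custom"),
            horizon=doc.get("horizon", 365.0),
            initial_marking=marking,
            param_overrides=doc.get("param_overrides", {}) or {},
        )
        if "ebv" in doc:
            kwargs["ebv_times"] = tuple(doc["ebv"].get("times", ()))
            kwargs["ebv_amount"] = doc["ebv"].get("amount", 1000.0)
        if "dac" in doc:
            kwargs["dac_time"] = doc["dac"].get("time")
            kwargs["dac_dose"] = doc["dac"].get("dose", 100.0)
            kwargs["dac_degradation_days"] = doc["dac"].get("degradation_days", 60.0)
        if "pregnancy" in doc:
            kwargs["pregnancy_start"] = doc["pregnancy"].get("start")
            kwargs["trimester_multiplier"] = doc["pregnancy"].get("trimester_multiplier", 1.0)
            kwargs["delivery_day"] = doc["pregnancy"].get("delivery_day", 273.0)
        return cls(**kwargs)


def default_scenario(label: str) -> ScenarioSpec:
    """The four reference protocols.

    ``healthy`` / ``ms``: the standard initial marking (500 fully
    myelinated ODC, 1687 resting Teff, 63 resting Treg, 375 NK, 1000 IL2)
    with five 1000-copy EBV injections every 60 days over one year.
    ``dac``: the MS protocol plus one daclizumab dose at day 53 after the
    first injection.  ``pregnancy``: the MS protocol with trimester phases
    shifting the Treg/Teff activation balance, delivery at day 273.
    """
    if label in ("healthy", "ms"):
        return ScenarioSpec(label=label)
    if label == "dac":
        return ScenarioSpec(label="dac", dac_time=53.0)
    if label == "pregnancy":
        return ScenarioSpec(label="pregnancy", pregnancy_start=0.0, trimester_multiplier=1.5)
    raise KeyError(f"unknown scenario label {label!r}")


def run_scenario(
    spec: ScenarioSpec,
    params: RRMSParameters | None = None,
    options: SolverOptions | None = None,
) -> tuple[Trajectory, UnfoldedSystem]:
    """Build, unfold and simulate a scenario; returns (trajectory, system)."""
    if params is None:
        params = default_parameters("healthy" if spec.label == "healthy" else "ms")
    if spec.dac_time is not None and spec.dac_degradation_days:
        # first-order degradation reaching ~99% at the configured span
        params = params.with_overrides(
            DACDegradation=float(np.log(100.0) / spec.dac_degradation_days)
        )
    if spec.param_overrides:
        params = params.with_overrides(**spec.param_overrides)
    net = build_rrms_net(params, include_dac=spec.uses_dac)
    net.m0 = spec.initial_marking.copy()
    system = unfold(net, params.as_dict())
    traj = simulate(
        system,
        schedule=spec.schedule(),
        horizon=spec.horizon,
        options=options,
        registry=rrms_registry(),
    )
    return traj, system


def default_parameter_space(
    label: str = "ms",
    parameters: Sequence[str] = CALIBRATION_PARAMETERS,
    span: float = 10.0,
) -> ParameterSpace:
    """Uniform LHS ranges for the calibration parameters: each range covers
    ``[default/span, default*span]`` around the selected parameter set."""
    base = default_parameters(label).as_dict()
    ranges = []
    for name in parameters:
        v = base[name]
        if v <= 0:
            raise ValueError(f"parameter {name} has non-positive default {v}")
        ranges.append((name, v / span, v * span))
    return ParameterSpace(tuple(ranges))


def lhs_prcc_workflow(
    n_samples: int,
    seed: int,
    label: str = "ms",
    parameters: Sequence[str] = CALIBRATION_PARAMETERS,
    times: Sequence[float] | None = None,
    span: float = 10.0,
    options: SolverOptions | None = None,
    alpha: float = 0.01,
):
    """The calibration workflow: LHS over the rate constants, one
    simulation per sample, time-resolved PRCC of irreversible ODC damage.

    Returns ``(design, result)`` where ``design`` is the LHS
    :class:`~essn.sensitivity.DesignMatrix` and ``result`` the
    :class:`~essn.sensitivity.PRCCResult` for the count of ODCs at the
    irreversible ``Lmin`` level.  The sweep runs on the net without the
    DAC module and with mildly relaxed solver tolerances (the output is a
    rank statistic, insensitive to fine integration error).
    """
    from .sensitivity import lhs_sample, prcc_over_time

    space = default_parameter_space(label, parameters, span)
    design = lhs_sample(space, n_samples, seed)
    base = default_parameters(label)
    net = build_rrms_net(base, include_dac=False)
    net.m0 = _standard_marking()
    system = unfold(net, base.as_dict())
    spec = default_scenario("ms")
    schedule = spec.schedule()
    options = options or SolverOptions(rtol=1e-4, atol=1e-6, grid_dt=5.0)
    registry = rrms_registry()
    trajectories = []
    for row in design.rows():
        traj = simulate(
            system,
            schedule=schedule,
            horizon=spec.horizon,
            options=options,
            registry=registry,
            params=row,
        )
        trajectories.append(traj)
    if times is None:
        times = np.arange(30.0, spec.horizon + 1.0, 30.0)

    def lmin_count(traj: Trajectory, t: float) -> float:
        return traj.value("ODC", t, ("Lmin",))

    result = prcc_over_time(design, trajectories, lmin_count, times, alpha=alpha)
    return design, result


# ---------------------------------------------------------------------------
# Outcome metrics
# ---------------------------------------------------------------------------


def pct_irreversible_odc(traj: Trajectory, nu: float) -> float:
    """Percentage of ODCs at the irreversible ``Lmin`` myelination level."""
    state = traj.at(nu)
    total = sum(
        state[traj.index.index("ODC", (lvl,))] for lvl in MYE_LEVELS
    )
    if total <= 0:
        raise ValueError(f"total ODC count is {total} at time {nu}")
    lmin = state[traj.index.index("ODC", ("Lmin",))]
    return 100.0 * lmin / total


def ebv_clearance_times(
    traj: Trajectory, threshold: float = 1.0
) -> list[tuple[int, float | None]]:
    """Per EBV injection, the delay until the viral load first falls below
    ``threshold`` (None if it never does within the horizon)."""
    inj_times = sorted(e["time"] for e in traj.events if e["place"] == "EBV")
    if not inj_times:
        return []
    ebv = traj.column("EBV")
    out: list[tuple[int, float | None]] = []
    for k, t0 in enumerate(inj_times):
        mask = traj.times > t0 + 1e-9
        below = mask & (ebv < threshold)
        if below.any():
            t_clear = float(traj.times[np.argmax(below)])
            out.append((k, t_clear - t0))
        else:
            out.append((k, None))
    return out
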