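"""Fluid (deterministic) semantics: speed laws, vector field, simulation.

The fluid approximation replaces the stochastic token game by ODEs on the
average token counts.  Every transition instance contributes its speed
times its incidence to the derivative of each state variable:

    dx[p,c]/dnu = sum over instances <t,b> of  F(x|inputs, t, b, nu) * L[p,b][c]

where F is the mass-action law (rate constant times the product of input
abundances raised to their arc multiplicities) for mass-action transitions
and a registered general function of the input marking and time for
general transitions.  An instance whose input states have been exhausted
(<= 0) contributes zero speed — the continuous analogue of enabling, which
also keeps trajectories from drifting negative.

Simulation is event-driven: integration proceeds piecewise between
impulse times (instantaneous additions of tokens, e.g. virus or drug
injections) and parameter-phase boundaries (piecewise-constant multipliers
on named rate constants, e.g. pregnancy trimesters), restarting the stiff
solver with the jumped state at each boundary.  Time is measured in days
and quantities in counts per reference volume.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import GeneralRate, Marking
from .unfolding import StateIndex, TransitionInstance, UnfoldedSystem

__all__ = [
    "GeneralRateRegistry",
    "EventSchedule",
    "Trajectory",
    "SolverOptions",
    "mass_action_speed",
    "transition_speed",
    "vector_field",
    "simulate",
]

# Contract for general rate functions:
#   fn(xhat, nu, params, binding) -> nonnegative speed
# where xhat maps (place, color tuple) -> value for the transition's input
# places only, nu is the time, params the resolved named parameters and
# binding the variable assignment of the instance.
GeneralRateFn = Callable[[Mapping, float, Mapping[str, float], Mapping[str, str]], float]


class GeneralRateRegistry:
    """Registry of general (non-mass-action) rate functions by identifier."""

    def __init__(self) -> None:
        self._fns: dict[str, GeneralRateFn] = {}

    def register(self, fn_id: str, fn: GeneralRateFn) -> None:
        self._fns[fn_id] = fn

    def __contains__(self, fn_id: str) -> bool:
        return fn_id in self._fns

    def get(self, fn_id: str) -> GeneralRateFn:
        if fn_id not in self._fns:
            raise KeyError(f"no general rate function registered under {fn_id!r}")
        return self._fns[fn_id]


def default_registry() -> GeneralRateRegistry:
    """Registry pre-loaded with common saturating kinetics."""
    reg = GeneralRateRegistry()

    def michaelis_menten(xhat, nu, params, binding):
        # single-substrate saturating law: Vmax * x / (K + x)
        ((_, x),) = [(k, v) for k, v in xhat.items()]
        return params["Vmax"] * x / (params["K"] + x)

    def hill(xhat, nu, params, binding):
        ((_, x),) = [(k, v) for k, v in xhat.items()]
        n = params.get("n", 2.0)
        return params["Vmax"] * x**n / (params["K"] ** n + x**n)

    reg.register("michaelis_menten", michaelis_menten)
    reg.register("hill", hill)
    return reg


# ---------------------------------------------------------------------------
# Events and schedules
# ---------------------------------------------------------------------------


@dataclass
class EventSchedule:
    """Impulse events and piecewise parameter phases.

    ``impulses`` are ``(time, place, color, amount)`` tuples: at that time
    the corresponding state jumps by ``amount`` (positive for injections).
    ``phases`` are ``(t0, t1, {parameter: multiplier})`` with the multiplier
    applied over the closed-open interval ``[t0, t1)``; intervals must not
    overlap per parameter.
    """

    impulses: list[tuple[float, str, tuple[str, ...], float]] = field(default_factory=list)
    phases: list[tuple[float, float, dict[str, float]]] = field(default_factory=list)

    def add_impulse(self, time: float, place: str, amount: float, color: tuple[str, ...] = ()) -> None:
        self.impulses.append((float(time), place, tuple(color), float(amount)))

    def add_phase(self, t0: float, t1: float, multipliers: Mapping[str, float]) -> None:
        self.phases.append((float(t0), float(t1), dict(multipliers)))

    def validate(self, horizon: float) -> None:
        for time, place, color, _ in self.impulses:
            if not (0.0 <= time <= horizon):
                raise ValueError(f"impulse at {time} outside [0, {horizon}]")
        per_param: dict[str, list[tuple[float, float]]] = {}
        for t0, t1, mults in self.phases:
            if t1 <= t0:
                raise ValueError(f"empty phase interval [{t0}, {t1})")
            for name in mults:
                per_param.setdefault(name, []).append((t0, t1))
        for name, ivals in per_param.items():
            ivals.sort()
            for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
                if b0 < a1:
                    raise ValueError(f"overlapping phases for parameter {name!r}")

    def multiplier(self, name: str, nu: float) -> float:
        out = 1.0
        for t0, t1, mults in self.phases:
            if t0 <= nu < t1 and name in mults:
                out *= mults[name]
        return out

    def breakpoints(self, horizon: float) -> list[float]:
        pts = {0.0, float(horizon)}
        pts.update(t for t, *_ in self.impulses if 0.0 <= t <= horizon)
        for t0, t1, _ in self.phases:
            if 0.0 <= t0 <= horizon:
                pts.add(t0)
            if 0.0 <= t1 <= horizon:
                pts.add(t1)
        return sorted(pts)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Time grid x state matrix produced by event-driven integration.

    At an impulse time the stored row is the right limit (post-jump); the
    pre-jump value is kept in the event annotations.
    """

    times: np.ndarray
    states: np.ndarray  # shape (len(times), n_states)
    index: StateIndex
    events: list[dict] = field(default_factory=list)

    def column(self, place: str, color: tuple[str, ...] = ()) -> np.ndarray:
        return self.states[:, self.index.index(place, color)]

    def at(self, nu: float) -> np.ndarray:
        """State at a grid time (exact match; linear interpolation between
        grid points); raises outside the grid range."""
        if nu < self.times[0] - 1e-9 or nu > self.times[-1] + 1e-9:
            raise ValueError(f"time {nu} outside trajectory grid [{self.times[0]}, {self.times[-1]}]")
        i = int(np.searchsorted(self.times, nu))
        if i < len(self.times) and abs(self.times[i] - nu) <= 1e-9:
            return self.states[i]
        if i > 0 and abs(self.times[i - 1] - nu) <= 1e-9:
            return self.states[i - 1]
        t0, t1 = self.times[i - 1], self.times[i]
        w = (nu - t0) / (t1 - t0)
        return (1 - w) * self.states[i - 1] + w * self.states[i]

    def value(self, place: str, nu: float, color: tuple[str, ...] = ()) -> float:
        return float(self.at(nu)[self.index.index(place, color)])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.index.labels())
        df.insert(0, "time", self.times)
        return df

    def events_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.events)


@dataclass
class SolverOptions:
    """Integrator settings: stiff-capable method, daily output grid."""

    method: str = "LSODA"
    rtol: float = 1e-6
    atol: float = 1e-9
    grid_dt: float = 1.0
    negativity_tol: float = 1e-3
    max_step: float = np.inf


# ---------------------------------------------------------------------------
# Speeds
# ---------------------------------------------------------------------------


def _resolve(value, params: Mapping[str, float], schedule: EventSchedule | None, nu: float) -> float:
    """A rate value is a number, or a parameter name subject to phase multipliers."""
    if isinstance(value, str):
        if value not in params:
            raise KeyError(f"unknown parameter {value!r}")
        v = params[value]
        if schedule is not None:
            v *= schedule.multiplier(value, nu)
        return v
    return float(value)


def mass_action_speed(xhat: Mapping, instance: TransitionInstance, omega: float) -> float:
    """Mass-action law: omega times the product of input-state abundances
    raised to their input-arc multiplicities.

    ``xhat`` maps state index -> value for the instance's input variables.
    Zero when any required input is zero; negative inputs beyond a small
    tolerance are rejected.
    """
    speed = float(omega)
    for idx, mult in instance.inputs.items():
        x = xhat[idx]
        if x < -1e-9:
            raise ValueError(
                f"negative state {x} at index {idx} while evaluating {instance.label}"
            )
        if x <= 0.0:
            return 0.0
        speed *= x**mult
    return speed


def _input_view(x: np.ndarray, instance: TransitionInstance, index: StateIndex) -> dict:
    """x restricted to the instance's input places, keyed (place, color)."""
    view = {}
    for place, color in index.pairs:
        if place in instance.input_places:
            view[(place, color)] = max(x[index.index(place, color)], 0.0)
    return view


def transition_speed(
    x: np.ndarray,
    nu: float,
    instance: TransitionInstance,
    index: StateIndex,
    registry: GeneralRateRegistry,
    params: Mapping[str, float],
    schedule: EventSchedule | None = None,
) -> float:
    """Speed of one transition instance at state ``x`` and time ``nu``.

    Dispatches to the mass-action law or to the registered general
    function; the result is clamped to be nonnegative and forced to zero
    whenever any net-consumed input state variable is <= 0 (the fluid
    analogue of enabling, which also prevents negative excursions).
    """
    for idx in instance.consumed:
        if x[idx] <= 0.0:
            return 0.0
    if instance.kind == "mass_action":
        omega = _resolve(instance.rate, params, schedule, nu)
        return mass_action_speed(x, instance, omega)
    spec = instance.rate
    assert isinstance(spec, GeneralRate)
    try:
        fn = registry.get(spec.fn_id)
    except KeyError:
        raise KeyError(
            f"transition {instance.transition!r} uses unregistered rate function {spec.fn_id!r}"
        ) from None
    fn_params = {k: _resolve(v, params, schedule, nu) for k, v in spec.params.items()}
    xhat = _input_view(x, instance, index)
    return max(fn(xhat, nu, fn_params, instance.binding), 0.0)


def vector_field(
    unfolded: UnfoldedSystem,
    x: np.ndarray,
    nu: float,
    params: Mapping[str, float] | None = None,
    schedule: EventSchedule | None = None,
    registry: GeneralRateRegistry | None = None,
) -> np.ndarray:
    """dx/dnu at state ``x`` and time ``nu``: the sum over transition
    instances of speed times incidence.  Pure function of its arguments."""
    params = dict(unfolded.params, **(params or {}))
    registry = registry or default_registry()
    dx = np.zeros(unfolded.n_states)
    for inst in unfolded.instances:
        speed = transition_speed(x, nu, inst, unfolded.index, registry, params, schedule)
        if speed:
            for idx, l in inst.incidence.items():
                dx[idx] += speed * l
    return dx


# ---------------------------------------------------------------------------
# Compiled right-hand side (used by simulate for performance)
# ---------------------------------------------------------------------------


class _CompiledRHS:
    """Per-segment compiled vector field: rates resolved once per segment."""

    def __init__(self, unfolded: UnfoldedSystem, registry: GeneralRateRegistry):
        self.unfolded = unfolded
        self.registry = registry
        self.n = unfolded.n_states
        self.ma: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, object]] = []
        self.gen: list[tuple[TransitionInstance, np.ndarray, GeneralRateFn, dict, np.ndarray, np.ndarray, dict]] = []
        for inst in unfolded.instances:
            in_idx = np.fromiter(inst.inputs.keys(), dtype=np.intp, count=len(inst.inputs))
            in_mult = np.fromiter(inst.inputs.values(), dtype=np.float64, count=len(inst.inputs))
            cons = inst.consumed
            c_idx = np.fromiter(cons.keys(), dtype=np.intp, count=len(cons))
            inc = inst.incidence
            l_idx = np.fromiter(inc.keys(), dtype=np.intp, count=len(inc))
            l_val = np.fromiter(inc.values(), dtype=np.float64, count=len(inc))
            if inst.kind == "mass_action":
                self.ma.append((in_idx, in_mult, l_idx, l_val, inst.rate, c_idx))
            else:
                fn = registry.get(inst.rate.fn_id)
                self.gen.append((inst, c_idx, fn, dict(inst.rate.params), l_idx, l_val, {}))
        self._views = [
            [
                (place, color, unfolded.index.index(place, color))
                for place, color in unfolded.index.pairs
                if place in inst.input_places
            ]
            for inst, *_ in self.gen
        ]
        self._ma_resolved: list[float] = []
        self._gen_resolved: list[dict] = []

    def resolve(self, params: Mapping[str, float], schedule: EventSchedule | None, nu: float) -> None:
        """Resolve rate constants and phase multipliers for a segment
        starting at (just after) ``nu``."""
        self._ma_resolved = [
            _resolve(rate, params, schedule, nu) for _, _, _, _, rate, _ in self.ma
        ]
        self._gen_resolved = [
            {k: _resolve(v, params, schedule, nu) for k, v in raw.items()}
            for _, _, _, raw, _, _, _ in self.gen
        ]

    def __call__(self, nu: float, x: np.ndarray) -> np.ndarray:
        dx = np.zeros(self.n)
        for (in_idx, in_mult, l_idx, l_val, _, c_idx), omega in zip(self.ma, self._ma_resolved):
            if c_idx.size and np.any(x[c_idx] <= 0.0):
                continue
            if in_idx.size:
                xi = np.maximum(x[in_idx], 0.0)
                speed = omega * np.prod(xi**in_mult)
            else:
                speed = omega
            if speed:
                dx[l_idx] += speed * l_val
        for (inst, c_idx, fn, _, l_idx, l_val, _), fp, view in zip(
            self.gen, self._gen_resolved, self._views
        ):
            if c_idx.size and np.any(x[c_idx] <= 0.0):
                continue
            xhat = {(p, c): max(x[i], 0.0) for p, c, i in view}
            speed = fn(xhat, nu, fp, inst.binding)
            if speed > 0.0:
                dx[l_idx] += speed * l_val
        return dx


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate(
    unfolded: UnfoldedSystem,
    m0: Marking | np.ndarray | None = None,
    schedule: EventSchedule | None = None,
    horizon: float = 365.0,
    options: SolverOptions | None = None,
    registry: GeneralRateRegistry | None = None,
    params: Mapping[str, float] | None = None,
) -> Trajectory:
    """Integrate the unfolded system over ``[0, horizon]`` with events.

    Integration restarts at every impulse time and phase boundary; at an
    impulse the state jumps by the scheduled amount.  Output is on a dense
    grid (default daily) that always includes the event times.  The run is
    deterministic given inputs and tolerances.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    schedule = schedule or EventSchedule()
    schedule.validate(horizon)
    options = options or SolverOptions()
    registry = registry or default_registry()
    all_params = dict(unfolded.params, **(params or {}))

    if m0 is None:
        x = unfolded.initial_state()
    elif isinstance(m0, Marking):
        x = unfolded.initial_state(m0)
    else:
        x = np.asarray(m0, dtype=float).copy()
        if x.shape != (unfolded.n_states,):
            raise ValueError(f"state vector has shape {x.shape}, expected ({unfolded.n_states},)")

    rhs = _CompiledRHS(unfolded, registry)

    grid = np.arange(0.0, horizon + options.grid_dt * 0.5, options.grid_dt)
    if grid[-1] < horizon - 1e-9:
        grid = np.append(grid, horizon)
    breakpoints = schedule.breakpoints(horizon)
    out_times = np.unique(np.concatenate([grid, np.asarray(breakpoints)]))

    impulses_at: dict[float, list[tuple[str, tuple[str, ...], float]]] = {}
    for time, place, color, amount in schedule.impulses:
        impulses_at.setdefault(float(time), []).append((place, color, amount))

    times_out: list[float] = []
    states_out: list[np.ndarray] = []
    events: list[dict] = []

    def apply_impulses(t: float) -> None:
        nonlocal x
        for place, color, amount in impulses_at.get(t, []):
            i = unfolded.index.index(place, color)
            before = x[i]
            x = x.copy()
            x[i] = before + amount
            events.append(
                {
                    "time": t,
                    "place": place,
                    "color": ",".join(color),
                    "amount": amount,
                    "before": before,
                    "after": x[i],
                }
            )

    # impulses exactly at 0 apply before integration starts
    apply_impulses(0.0)
    times_out.append(0.0)
    states_out.append(x.copy())

    seg_bounds = breakpoints
    out_list = out_times.tolist()
    for t0, t1 in zip(seg_bounds, seg_bounds[1:]):
        rhs.resolve(all_params, schedule, t0)
        lo = bisect.bisect_right(out_list, t0 + 1e-12)
        hi = bisect.bisect_left(out_list, t1 - 1e-12)
        t_eval = [t for t in out_times[lo:hi]] + [t1]
        sol = solve_ivp(
            rhs,
            (t0, t1),
            x,
            method=options.method,
            rtol=options.rtol,
            atol=options.atol,
            max_step=options.max_step,
            t_eval=np.asarray(t_eval),
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed on [{t0}, {t1}]: {sol.message}"
            )
        low = sol.y.min()
        if low < -options.negativity_tol:
            raise RuntimeError(
                f"state fell below -{options.negativity_tol} (min {low}) on [{t0}, {t1}]"
            )
        x = sol.y[:, -1].copy()
        # record interior points and the segment end (post-impulse below)
        for j, t in enumerate(sol.t[:-1]):
            times_out.append(float(t))
            states_out.append(sol.y[:, j].copy())
        apply_impulses(t1)
        times_out.append(float(t1))
        states_out.append(x.copy())

    return Trajectory(
        times=np.asarray(times_out),
        states=np.vstack(states_out),
        index=unfolded.index,
        events=events,
    )
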