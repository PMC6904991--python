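# Methods

## Model and semantics

`essn` implements colored stochastic Petri nets in their deterministic
(fluid) reading.  A net declares finite color classes (optionally ordered,
with a circular successor, and partitioned into static subclasses), places
typed by color domains, and guarded transitions whose arcs carry
expressions built from variables, `succ^k`/`pred^k` of variables of
ordered classes, and constant colors.  Transitions split into a
mass-action set and a general set; the latter's speeds are arbitrary
registered functions restricted, by contract, to the marking of the
transition's input places and the current time.

Unfolding materializes one state variable per (place, color) pair —
places in declaration order, colors in lexicographic element order, so
indices, instance order and every downstream output are deterministic —
and one transition instance per guard-legal binding.  Instances excluded
by their guard are never created; the packaged RRMS net therefore unfolds
to exactly 13 ODEs without its daclizumab module (14 with it), with 25
(27) transition instances.

The vector field sums, per state variable, instance speed times incidence
(L = O − I).  Two semantic choices deserve note:

* **Continuous enabling.**  An instance's speed is forced to zero when
  any *net-consumed* input (I > O) is exhausted (≤ 0).  Side conditions —
  read arcs with I = O — are deliberately exempt: a catalytic side
  condition already appears as a factor of the rate law and vanishes with
  the population, while an *inhibitory* read arc (daclizumab's arc onto
  the duplication transitions) must not disable its target when the
  inhibitor is absent.  Restricting the check to consumed inputs is also
  exactly what is needed to prevent negative excursions.
* **Impulse dosing.**  Injections (virus, drug) are instantaneous state
  jumps, not always-on source transitions: integration restarts at every
  impulse time and phase boundary.  The `EBVinj`/`DACinj` transitions
  remain in the net as documentation with zero continuous rate.

Integration uses `scipy.integrate.solve_ivp` with LSODA, rtol 1e-6,
atol 1e-9, and a daily output grid by default; the sensitivity sweep
relaxes to rtol 1e-4 / atol 1e-6 (its output feeds a rank statistic, so
fine integration error is immaterial).  Time is in days; quantities are
counts per reference volume (cells or particles per mm³).  Trajectories
store the right limit at impulse times; the pre-jump value is kept in the
event log.

## Sensitivity analysis

LHS partitions each parameter's uniform range into N equal-probability
strata, draws one uniform sample per stratum and pairs strata across
parameters through independent seeded permutations.  The PRCC of
parameter j against an output rank-transforms every column (average
ranks on ties), regresses the target column and the output on the other
k columns (OLS with intercept), and correlates the residuals; the
p-value uses t = r·sqrt((N−2−k)/(1−r²)) with N−2−k degrees of freedom.
A correlation-matrix-inverse formulation serves as the independent test
oracle.  The default significance level for the time-resolved
non-significance band is α = 0.01 with no multiple-testing correction
(Bonferroni across parameters is available as an option).

## The RRMS model

Seven modules over 10 places and 22 transitions.  `ODC` is colored by
the ordered class `Mye` = (Lmin, L1, L2, L3, Lmax) with singleton static
subclasses; effector attack (`TeffKillsODC`) moves an ODC one level down
and is guarded by `not (l in Lmin)`; remyelination moves one level up
and is guarded to exclude both `Lmin` (irreversible damage is absorbing)
and `Lmax` (a fully myelinated cell cannot gain a level — the formal
description leaves this case open; excluding it also keeps the circular
successor from wrapping).  Effector duplication is symmetric (two Teff)
with probability `p_eff_dup` and asymmetric (one Teff, one memory cell)
with the complement; both consume IL2, as do Treg and NK proliferation,
and IL2 is produced in bursts of `il2_per_activation` (default 25)
molecules per effector activation.  Thymic output transitions replenish
the resting pools toward their set-points (1687 Teff, 63 Treg).
Daclizumab multiplies the three duplication speeds by 1/(1 + x_DAC/K_DAC)
and degrades first-order, with the rate expressed as ln(100)/T so that a
"persistence" of T ∈ [30, 90] days means ~99% degradation by T.

General kinetics are saturating (Michaelis-Menten-like) stand-ins with
configurable half-saturation constants: the original study defines its
general functions in unpublished supplementary material, so the forms
here are the package's own and are clearly scoped to one registry
(`rrms_registry`).

### Scenarios

All four protocols start from 500 ODC at `Lmax`, 1687 resting Teff, 63
resting Treg, 375 NK and 1000 IL2, with five 1000-copy EBV injections at
days 0, 60, 120, 180, 240 and a 365-day horizon.  `dac` adds a single
300-unit dose at day 53 after the first injection (the cited clinical
trial doses every 4 weeks; the packaged protocol is the single
administration, and repeated dosing is a one-line schedule change).
`pregnancy` applies per-trimester multiplicative phases — trimester i
scales `TregActivation` by m^i and `TeffActivation` by m^-i — with
boundaries at days 0/91/182, delivery at day 273 and both rates reset
thereafter.

### Calibration of the default parameter sets

The published rate constants live in an unavailable supplement, so the
packaged `healthy` and `ms` sets were calibrated against the published
*outcomes*: the `ms` set reproduces the disease endpoint (77% of ODCs
irreversibly damaged at day 365) and partial viral control; the
`healthy` set clears every injection within days, shows the
memory-accelerated secondary response, and keeps damage small and
dose-bounded across injected amounts of 1000–5000/mm³ (maximum ≈ 2%,
comfortably inside the published 17% bound, which the package treats as
an upper limit).  Two calibration facts are load-bearing:

* **NK cells must compete for IL2** (`NKdup` ≈ 1.3e-4).  If T-cell
  duplication were the only IL2 sink, the total number of duplication
  events would be fixed by the IL2 budget and daclizumab would merely
  spread the same effector expansion over a longer infection — leaving
  final damage unchanged or worse.  With NK proliferation as a competing,
  un-inhibited consumer, DAC genuinely shrinks the effector expansion
  (and NK counts rise under therapy, as observed).
* **Viral clearance is activation-driven and fast** (`TeffKillsEBV` on
  the order of 1e-2).  This keeps exposure duration roughly constant
  across interventions, so interventions that damp the effector burst
  (DAC, pregnancy) reduce damage instead of prolonging the infection.

With these defaults the trend checks hold on a grid: final damage is
non-increasing in DAC persistence over 30/60/90 days and below the
untreated course; pregnancy damage stays at or below baseline with a
protection gap growing toward delivery; clearance of the second episode
is faster than the first.

## What the packaged model does and does not show

The synthetic protocols emulate the study conditions (initial marking,
injection schedule, horizon, LHS design sizes), not patient data: passing
tests demonstrate that the formalism, the unfolding, the integrator and
the sensitivity machinery reproduce the model's published structure and
qualitative behaviour under a calibration chosen to match published
endpoints.  They say nothing about the biological fidelity of the
stand-in kinetics or constants, and real-data features — measurement
noise, patient heterogeneity, spatial structure — are out of scope.

## Numerical and scale choices

The test suite and reproduction scripts run everything at reduced scale
chosen for convergence, not fidelity limits: 200 LHS samples (published:
5000) over the nine calibration rate constants, 40-sample dose sweeps
(published: 500), PRCC on a 30-day grid.  PRCC values at these sizes are
stable to well under the 0.05 level at which they are interpreted.
Deterministic runs are bit-reproducible given identical seeds,
tolerances and inputs; the single RNG entry point is
`numpy.random.default_rng(seed)` inside `lhs_sample` and the fixture
generator.

## Known limitations

* Stochastic (CTMC) firing semantics, SSA/τ-leaping and hybrid switching
  are not implemented; the package is the deterministic pipeline.
* General rate functions are trusted to honour the input-place contract;
  it is asserted structurally (the view passed to them is restricted)
  but not verified symbolically.
* No symmetry-exploiting (lumped) unfolding: equivalent colors are
  enumerated explicitly.
* The net document dialect is this package's own; GreatSPN `.net/.def`
  import is not provided.
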