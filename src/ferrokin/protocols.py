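"""Simulation protocols and derived tracer observables.

The experimental template is a classical ferrokinetic study: animals are
held on a given diet long enough for the body iron pools to reach a quasi
steady state, a small radioactive iron dose is injected into the plasma,
and the fraction of the injected dose in each compartment is followed for
about four weeks.  This module reproduces that template in silico:

* ``quasi_steady_state`` / ``steady_state`` -- lead-in equilibration,
* ``inject_tracer`` -- instantaneous dose into plasma NTBI,
* ``run`` -- stiff integration returning a :class:`Trajectory` with
  fraction-of-dose observables per reported pool,
* ``apply_diet`` -- the two-parameter diet switch (dietary influx and
  hepcidin synthesis; everything else is locked),
* ``anemia_protocol`` -- chronic hepcidin elevation over a year,
* ``transition_time`` -- steady-state pool content over throughput.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .model import (
    IRON_CONTENT,
    IRON_MOLAR_MASS,
    LABEL_CONTENT,
    SPECIES_COMPARTMENT,
    ModelSpec,
    ParameterSet,
    build_model,
    labeled_iron_mol,
    tf_saturation,
    total_iron,
)

logger = logging.getLogger("ferrokin")

#: the eight pools reported in a ferrokinetic experiment
REPORTED_POOLS: Tuple[str, ...] = (
    "plasma", "duodenum", "bone_marrow", "rbc", "liver", "spleen", "rest",
    "excreted",
)

#: default observation grid (days): dense over the fast plasma clearance
#: phase, then weekly out to four weeks
DEFAULT_OBSERVATION_DAYS: Tuple[float, ...] = (
    0.01, 0.04, 0.17, 0.5, 1.0, 2.0, 4.0, 7.0, 10.0, 14.0, 21.0, 28.0)

DEFAULT_LEADIN_DAYS = 5000.0
DIET_LEADIN_DAYS = 35.0  # experimental diets run 5 weeks before the pulse


@dataclass
class Protocol:
    """Configuration of a tracer experiment."""

    leadin_days: float = DEFAULT_LEADIN_DAYS
    diet_leadin_days: float = DIET_LEADIN_DAYS
    injection_dose_mol: Optional[float] = None  # default: 1e-4 x plasma iron
    observation_days: Tuple[float, ...] = DEFAULT_OBSERVATION_DAYS
    diet_vDiet: Optional[float] = None
    diet_kHepSyn: Optional[float] = None
    horizon_days: Optional[float] = None

    def __post_init__(self):
        if self.leadin_days < 0 or self.diet_leadin_days < 0:
            raise ValueError("lead-in durations must be nonnegative")
        if self.injection_dose_mol is not None and self.injection_dose_mol < 0:
            raise ValueError("injection dose must be nonnegative")
        if any(t < 0 for t in self.observation_days):
            raise ValueError("observation times must be nonnegative")


class IntegrationError(RuntimeError):
    """Raised when the stiff integrator fails; carries the last good time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last successful time: {last_time:g} d)")
        self.last_time = last_time


class BudgetExceeded(IntegrationError):
    """Raised when one integration burns through its RHS-evaluation budget
    (pathological parameter regions can make the system arbitrarily stiff;
    the calibration objective treats this as a failed, penalized point)."""


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def integrate(fun, y0: np.ndarray, times: Sequence[float], rtol: float = 1e-8,
              atol: float = 1e-12, method: str = "LSODA",
              max_rhs_evals: Optional[int] = 150_000) -> np.ndarray:
    """Integrate ``fun(t, y)`` over ``times`` and return states row-wise.

    ``max_rhs_evals`` bounds the work per call: extreme parameter
    combinations can make the system so stiff that the solver crawls, and
    a capped integration raising :class:`BudgetExceeded` is preferable to
    an unbounded one during optimization sweeps.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or (times.size >= 1 and times[-1] == times[0]):
        return np.tile(np.asarray(y0, dtype=float), (max(times.size, 1), 1))
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be increasing")
    t0 = times[0]
    if max_rhs_evals is not None:
        budget = max_rhs_evals
        inner = fun

        def fun(t, y, _inner=inner):
            nonlocal budget
            budget -= 1
            if budget < 0:
                raise BudgetExceeded("RHS evaluation budget exceeded", t)
            return _inner(t, y)

    sol = solve_ivp(fun, (t0, times[-1]), np.asarray(y0, dtype=float),
                    t_eval=times, method=method, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(sol.message,
                               float(sol.t[-1]) if len(sol.t) else t0)
    return sol.y.T


def _guarded(states: np.ndarray, floor: float = -1e-8) -> np.ndarray:
    """Clip integrator round-off below zero; loudly reject real negativity."""
    m = states.min()
    if m < floor:
        logger.warning("trajectory dipped to %g; clipping to zero", m)
    return np.clip(states, 0.0, None)


@dataclass
class Trajectory:
    """Integrated states plus the derived tracer observables."""

    model: ModelSpec
    times: np.ndarray
    states: np.ndarray  # (n_times, n_species)
    injected_dose_mol: Optional[float] = None

    # -- derived observables ----------------------------------------------
    def tracer_amounts(self) -> pd.DataFrame:
        """Radioactive iron amount (mol) per reported pool over time."""
        if not self.model.include_tracer:
            raise ValueError("tracer observables need a tracer-enabled model")
        ix = self.model.index
        vp = self.model.compartments["plasma"].volume
        y = self.states
        cols = {
            "plasma": (y[:, ix("NTBI*")] + y[:, ix("Fe1Tf*")]
                       + y[:, ix("Fe2Tf*")] + 2.0 * y[:, ix("Fe2Tf**")]) * vp,
            "excreted": y[:, ix("FeOutside*")],
        }
        for pool, sp in (("duodenum", "FeDuo*"), ("bone_marrow", "FeBM*"),
                         ("rbc", "FeRBC*"), ("liver", "FeLiver*"),
                         ("spleen", "FeSpleen*"), ("rest", "FeRest*")):
            cols[pool] = y[:, ix(sp)] * self.model.volume(sp)
        return pd.DataFrame(cols, index=self.times)[list(REPORTED_POOLS)]

    def tracer_fractions(self) -> pd.DataFrame:
        """Fraction of the injected dose per reported pool over time."""
        if not self.injected_dose_mol:
            raise ValueError("no injected dose recorded for this trajectory")
        return self.tracer_amounts() / self.injected_dose_mol

    def total_iron_mg(self, include_outside: bool = False) -> np.ndarray:
        return np.array([total_iron(y, self.model, include_outside)
                         for y in self.states])

    def tf_saturation_pct(self) -> np.ndarray:
        return np.array([tf_saturation(y, self.model) for y in self.states])

    def hepcidin_nM(self) -> np.ndarray:
        return self.states[:, self.model.index("Hepcidin")] * 1e9

    def to_tidy(self) -> pd.DataFrame:
        """Tidy export: time_days, pool/species, value_kind, value."""
        rows = []
        if self.model.include_tracer and self.injected_dose_mol:
            frac = self.tracer_fractions()
            for pool in frac.columns:
                for t, v in zip(self.times, frac[pool].to_numpy()):
                    rows.append((t, pool, "fraction_of_dose", v))
        for j, s in enumerate(self.model.species):
            kind = ("amount_mol" if SPECIES_COMPARTMENT[s] == "outside"
                    else "concentration_M")
            for t, v in zip(self.times, self.states[:, j]):
                rows.append((t, s, kind, v))
        return pd.DataFrame(rows, columns=["time_days", "pool", "value_kind",
                                           "value"])

    def to_csv(self, path) -> None:
        self.to_tidy().to_csv(path, index=False)


def run(model: ModelSpec, initial_state: np.ndarray,
        times: Sequence[float], rtol: float = 1e-10, atol: float = 1e-14,
        injected_dose_mol: Optional[float] = None) -> Trajectory:
    """Integrate the model over ``times`` from ``initial_state``."""
    states = integrate(model.rhs, initial_state, times, rtol=rtol, atol=atol)
    return Trajectory(model=model, times=np.asarray(times, dtype=float),
                      states=_guarded(states), injected_dose_mol=injected_dose_mol)


# ---------------------------------------------------------------------------
# Steady states and injection
# ---------------------------------------------------------------------------

def qss_residual(model: ModelSpec, y: np.ndarray) -> float:
    """Relative derivative norm |dy/dt| / (|y| + eps), excreted pools excluded."""
    dydt = model.rhs(0.0, y)
    keep = np.array([SPECIES_COMPARTMENT[s] != "outside"
                     for s in model.species])
    num = np.linalg.norm(dydt[keep])
    den = np.linalg.norm(y[keep]) + 1e-300
    return float(num / den)


def quasi_steady_state(model: ModelSpec, start_state: Optional[np.ndarray] = None,
                       leadin_days: float = DEFAULT_LEADIN_DAYS,
                       rtol: float = 1e-8, atol: float = 1e-14) -> np.ndarray:
    """State after a lead-in integration of ``leadin_days``.

    The non-tracer subsystem settles to a genuine steady state (diet influx
    balanced by duodenal/skin losses); the residual relative derivative
    norm is logged so drifting lead-ins are visible.
    """
    if leadin_days <= 0:
        raise ValueError("leadin_days must be positive")
    if start_state is None:
        start_state = model.initial_state()
    states = integrate(model.rhs, start_state, (0.0, leadin_days),
                       rtol=rtol, atol=atol)
    y = _guarded(states)[-1]
    logger.info("lead-in of %g d: residual relative derivative %.3e",
                leadin_days, qss_residual(model, y))
    return y


def steady_state(model: ModelSpec, start_state: Optional[np.ndarray] = None,
                 leadin_days: float = DEFAULT_LEADIN_DAYS) -> np.ndarray:
    """Lead-in integration polished by a root solve (fast, accurate path).

    Excreted (outside) pools keep their post-lead-in values: they grow
    secularly and are excluded from the root condition.
    """
    y = quasi_steady_state(model, start_state, leadin_days, rtol=1e-6,
                           atol=1e-12)
    free = np.array([SPECIES_COMPARTMENT[s] != "outside"
                     for s in model.species])
    idx = np.where(free)[0]

    def resid(x):
        full = y.copy()
        full[idx] = x
        return model.rhs(0.0, full)[idx]

    sol = root(resid, y[idx], method="hybr", options={"xtol": 1e-12})
    if sol.success and np.all(sol.x >= -1e-15):
        y = y.copy()
        y[idx] = np.clip(sol.x, 0.0, None)
    else:
        logger.debug("steady-state polish rejected (%s); keeping lead-in state",
                     getattr(sol, "message", "failure"))
    return y


def inject_tracer(model: ModelSpec, state: np.ndarray,
                  dose_mol: float) -> np.ndarray:
    """Add a radioactive dose (mol) to plasma NTBI*; everything else unchanged."""
    if dose_mol < 0:
        raise ValueError("dose must be nonnegative")
    y = np.array(state, dtype=float)
    vp = model.compartments["plasma"].volume
    y[model.index("NTBI*")] += dose_mol / vp
    return y


def default_dose(model: ModelSpec, state: np.ndarray,
                 relative: float = 1e-7) -> float:
    """A dose small enough to leave total iron essentially unperturbed.

    Defaults to 1e-7 of the plasma iron amount at the pre-injection state,
    deep in the linear regime of the tracer subsystem: fraction-of-dose
    observables are then invariant to the exact dose to ~1e-6 relative
    (a larger dose measurably perturbs the apo-transferrin background).
    """
    ix = model.index
    vp = model.compartments["plasma"].volume
    plasma_iron = (state[ix("NTBI")] + state[ix("Fe1Tf")]
                   + 2.0 * state[ix("Fe2Tf")]) * vp
    return relative * float(plasma_iron)


def tracer_atol(model: ModelSpec, dose_mol: float,
                base_atol: float = 1e-14) -> np.ndarray:
    """Per-species absolute tolerances scaled to the tracer dose.

    Labeled concentrations live many orders of magnitude below the bulk
    iron pools, so their error floor must track the dose for the
    fraction-of-dose observables to stay accurate.
    """
    vp = model.compartments["plasma"].volume
    tracer_scale = max(dose_mol / vp, 1e-300)
    atol = np.full(model.n_species, base_atol)
    for i, s in enumerate(model.species):
        if LABEL_CONTENT[s]:
            atol[i] = 1e-9 * tracer_scale
    return atol


def tracer_experiment(params: ParameterSet,
                      observation_days: Sequence[float] = DEFAULT_OBSERVATION_DAYS,
                      leadin_days: float = DEFAULT_LEADIN_DAYS,
                      diet: Optional[Dict[str, float]] = None,
                      diet_leadin_days: float = DIET_LEADIN_DAYS,
                      base_state: Optional[np.ndarray] = None,
                      rtol: float = 1e-10) -> Trajectory:
    """Full protocol: equilibrate, optionally switch diet, inject, observe.

    ``diet`` may override ``vDiet`` and/or ``kHepSyn`` (only); the switch is
    applied ``diet_leadin_days`` before the tracer pulse, mirroring the
    5-week dietary conditioning of the experiment.
    """
    plain = build_model(params, include_tracer=False)
    if base_state is None:
        y_plain = steady_state(plain, leadin_days=leadin_days)
    else:
        y_plain = np.asarray(base_state, dtype=float)

    work_params = params
    if diet:
        work_params = _diet_params(params, **diet)
        plain = apply_diet(plain, vDiet=work_params.vDiet,
                           kHepSyn=work_params.kHepSyn)
        y_plain = integrate(plain.rhs, y_plain, (0.0, diet_leadin_days),
                            rtol=rtol, atol=1e-14)[-1]

    tracer = build_model(work_params, include_tracer=True)
    y0 = np.zeros(tracer.n_species)
    for i, s in enumerate(plain.species):
        y0[tracer.index(s)] = y_plain[i]
    dose = default_dose(tracer, y0)
    y0 = inject_tracer(tracer, y0, dose)
    times = np.asarray(observation_days, dtype=float)
    if times[0] > 0.0:
        times = np.concatenate(([0.0], times))
    traj = run(tracer, y0, times, rtol=rtol,
               atol=tracer_atol(tracer, dose), injected_dose_mol=dose)
    return traj


# ---------------------------------------------------------------------------
# Diet switching
# ---------------------------------------------------------------------------

def _diet_params(params: ParameterSet, vDiet: Optional[float] = None,
                 kHepSyn: Optional[float] = None, **other) -> ParameterSet:
    if other:
        raise ValueError(
            f"a diet may only change vDiet and kHepSyn, not {sorted(other)}")
    updates = {}
    if vDiet is not None:
        updates["vDiet"] = vDiet
    if kHepSyn is not None:
        updates["kHepSyn"] = kHepSyn
    return params.replace(**updates) if updates else params


def apply_diet(model: ModelSpec, vDiet: Optional[float] = None,
               kHepSyn: Optional[float] = None) -> ModelSpec:
    """Return a model on a new diet: only vDiet and kHepSyn may change."""
    return model.with_params(_diet_params(model.params, vDiet, kHepSyn))


# ---------------------------------------------------------------------------
# Transition time
# ---------------------------------------------------------------------------

_POOL_COMPARTMENT = {
    "plasma": "plasma", "duodenum": "duodenum", "bone_marrow": "bone_marrow",
    "rbc": "rbc", "liver": "liver", "spleen": "spleen", "rest": "rest",
}


def compartment_iron_amount(model: ModelSpec, y: np.ndarray,
                            compartment: str) -> float:
    """Iron amount (mol) homed in one compartment at state ``y``."""
    from .model import IRON_CONTENT
    total = 0.0
    for i, s in enumerate(model.species):
        if SPECIES_COMPARTMENT[s] == compartment:
            total += IRON_CONTENT[s] * y[i] * model.volume(s)
    return total


def compartment_iron_outflow(model: ModelSpec, y: np.ndarray,
                             compartment: str) -> float:
    """Total iron flux (mol/day) leaving one compartment at state ``y``."""
    from .model import IRON_CONTENT
    out = 0.0
    for r in model.reactions:
        flux = model.reaction_flux(r, y)
        for s, nu in r.stoich.items():
            if nu < 0 and SPECIES_COMPARTMENT[s] == compartment:
                out += -nu * IRON_CONTENT[s] * flux
    return out


def transition_time(params: ParameterSet, pool: str = "rbc",
                    leadin_days: float = DEFAULT_LEADIN_DAYS) -> float:
    """Mean residence time of iron in a pool: content / throughput (days).

    Both quantities are evaluated by reaction-level bookkeeping at the
    adequate-diet steady state.  For the RBC pool, whose single exit is
    first order, this reduces analytically to 1/vRBCSpleen -- the mean
    erythrocyte iron residence time.
    """
    comp = _POOL_COMPARTMENT.get(pool)
    if comp is None:
        raise ValueError(f"unknown pool {pool!r}")
    model = build_model(params, include_tracer=False)
    y = steady_state(model, leadin_days=leadin_days)
    content = compartment_iron_amount(model, y, comp)
    outflow = compartment_iron_outflow(model, y, comp)
    if outflow <= 0.0 or not np.isfinite(outflow):
        raise ZeroDivisionError(
            f"pool {pool!r} has no steady-state throughput; "
            "transition time undefined")
    return content / outflow


# ---------------------------------------------------------------------------
# Anemia of chronic disease
# ---------------------------------------------------------------------------

@dataclass
class AnemiaReport:
    """Outcome of a chronic hepcidin-elevation simulation."""

    trajectory: Trajectory
    fold_changes: Dict[str, float]  # final/initial iron per pool + total
    peak_values: Dict[str, float]
    peak_times: Dict[str, float]


def anemia_protocol(model: ModelSpec, hepcidin_fold: float = 5.0,
                    horizon_days: float = 365.0,
                    n_points: int = 732) -> AnemiaReport:
    """Simulate anemia of chronic disease from the adequate steady state.

    Hepcidin synthesis is scaled so the hormone settles at ``hepcidin_fold``
    times its baseline, and the (tracer-free) model is run for a year.
    Reported per-pool fold changes are final/initial iron; spleen and liver
    show transient overshoots, so their peak values and times are returned
    too.
    """
    if model.include_tracer:
        model = build_model(model.params, include_tracer=False)
    y0 = steady_state(model)
    sick = model.with_params(
        model.params.replace(kHepSyn=model.params.kHepSyn * hepcidin_fold))
    times = np.linspace(0.0, horizon_days, n_points)
    traj = run(sick, y0, times)

    pools = {p: _POOL_COMPARTMENT[p] for p in _POOL_COMPARTMENT}
    series: Dict[str, np.ndarray] = {}
    for pool, comp in pools.items():
        series[pool] = np.array([
            compartment_iron_amount(sick, y, comp) for y in traj.states])
    series["total"] = traj.total_iron_mg() / (IRON_MOLAR_MASS * 1e3)

    fold, peaks, peak_t = {}, {}, {}
    for pool, vals in series.items():
        init = vals[0] if vals[0] > 0 else np.finfo(float).tiny
        fold[pool] = float(vals[-1] / init)
        j = int(np.argmax(vals))
        peaks[pool] = float(vals[j] / init)
        peak_t[pool] = float(times[j])
    return AnemiaReport(trajectory=traj, fold_changes=fold,
                        peak_values=peaks, peak_times=peak_t)


# ---------------------------------------------------------------------------
# Hepcidin inhibition-constant calibration
# ---------------------------------------------------------------------------

def fit_hepcidin_ki(params: ParameterSet, target_total_fe_mg: float = 2.2,
                    log10_bounds: Tuple[float, float] = (-10.5, -7.0)) -> float:
    """Solve for the hepcidin inhibition constant Ki (M).

    The source ferrokinetic dataset fixes the adequate-diet steady state
    (total body iron ~2.2 mg at a 23 nM hepcidin level), but Ki itself is
    not identifiable from tracer fractions alone.  This closes the model:
    find the Ki at which the adequate-diet steady state carries the target
    total iron.  Total iron decreases monotonically with Ki (weaker
    inhibition lets ferroportin drain the tissues), so a bracketed scalar
    solve on log10(Ki) is well posed.
    """

    def excess(log10_ki: float) -> float:
        m = build_model(params.replace(Ki=10.0 ** log10_ki),
                        include_tracer=False)
        y = steady_state(m)
        return total_iron(y, m) - target_total_fe_mg

    lo, hi = log10_bounds
    return 10.0 ** brentq(excess, lo, hi, xtol=1e-6)
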