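"""Constrained parameter estimation against tracer datasets.

The estimation problem mirrors the original calibration: minimize the sum
of squared residuals between simulated and observed fraction-of-dose
time courses, subject to the nonlinear constraint that total body iron at
the moment of tracer injection lies in a physiological window (2 +/- 0.2
mg by default).  The workhorse optimizer is an evolution strategy with
stochastic ranking (SRES), the method that handles such nonlinear
constraints gracefully; a Hooke--Jeeves pattern search provides
derivative-free local refinement.  Rate constants span many orders of
magnitude, so the search runs in log10 space.

Joint (multi-diet) fits share every parameter across diets except the
dietary influx ``vDiet`` and the hepcidin synthesis rate ``kHepSyn``,
which are the only condition-specific degrees of freedom the regulation
hypothesis allows.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelSpec, ParameterSet, build_model, tf_saturation, total_iron
from .protocols import (
    DEFAULT_LEADIN_DAYS,
    DIET_LEADIN_DAYS,
    IntegrationError,
    compartment_iron_amount,
    compartment_iron_outflow,
    default_dose,
    inject_tracer,
    integrate,
    run,
    steady_state,
    tracer_atol,
)
from .synthetic import TracerDataset

logger = logging.getLogger("ferrokin")

PENALTY_SSQ = 1e6  # objective value assigned to failed simulations

PER_DIET_ALLOWED = ("vDiet", "kHepSyn")


@dataclass
class DatasetSpec:
    """One dataset plus the dietary condition it was measured under.

    ``overrides`` fixes vDiet/kHepSyn for this diet when they are not
    freed per-diet; the adequate condition uses the shared parameters.
    """

    dataset: TracerDataset
    diet: str = "adequate"
    overrides: Optional[Dict[str, float]] = None

    def __post_init__(self):
        if self.overrides:
            bad = set(self.overrides) - set(PER_DIET_ALLOWED)
            if bad:
                raise ValueError(
                    f"diet overrides may only touch {PER_DIET_ALLOWED}, "
                    f"not {sorted(bad)}")


@dataclass
class FitProblem:
    """Free parameters, bounds, datasets and the total-iron constraint."""

    base: ParameterSet
    free: Tuple[str, ...]
    bounds: Dict[str, Tuple[float, float]]
    datasets: List[DatasetSpec]
    per_diet_free: Tuple[str, ...] = ()
    constraint_mg: Tuple[float, float] = (1.8, 2.2)
    leadin_days: float = DEFAULT_LEADIN_DAYS
    diet_leadin_days: float = DIET_LEADIN_DAYS
    weighted: bool = False
    sim_rtol: float = 1e-8

    def __post_init__(self):
        valid = set(ParameterSet.names())
        for name in self.free:
            if name not in valid:
                raise ValueError(f"unknown free parameter {name!r}")
        bad = set(self.per_diet_free) - set(PER_DIET_ALLOWED)
        if bad:
            raise ValueError(
                f"only {PER_DIET_ALLOWED} may vary per diet, not {sorted(bad)}")
        for name in tuple(self.free) + tuple(self.per_diet_free):
            lo, hi = self.bounds[name]
            if not (0 < lo < hi):
                raise ValueError(f"bounds for {name!r} must be 0 < lo < hi")
        if not self.datasets:
            raise ValueError("at least one dataset is required")
        if self.weighted and not all(d.dataset.has_sd for d in self.datasets):
            raise ValueError("weighted fitting needs sd on every dataset")

    # -- parameter-vector layout ------------------------------------------
    @property
    def theta_names(self) -> Tuple[str, ...]:
        names = list(self.free)
        for i, ds in enumerate(self.datasets):
            for p in self.per_diet_free:
                names.append(f"{p}[{ds.diet}#{i}]")
        return tuple(names)

    @property
    def n_theta(self) -> int:
        return len(self.free) + len(self.per_diet_free) * len(self.datasets)

    def log_bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        los, his = [], []
        for name in self.free:
            lo, hi = self.bounds[name]
            los.append(math.log10(lo)); his.append(math.log10(hi))
        for _ in self.datasets:
            for p in self.per_diet_free:
                lo, hi = self.bounds[p]
                los.append(math.log10(lo)); his.append(math.log10(hi))
        return np.array(los), np.array(his)

    def split(self, theta_log: np.ndarray) -> Tuple[ParameterSet, List[Dict[str, float]]]:
        """Decode a log10 parameter vector into shared + per-diet values."""
        vals = 10.0 ** np.asarray(theta_log, dtype=float)
        shared = self.base.replace(**dict(zip(self.free, vals[: len(self.free)])))
        per_diet: List[Dict[str, float]] = []
        k = len(self.free)
        for _ in self.datasets:
            d = {}
            for p in self.per_diet_free:
                d[p] = float(vals[k]); k += 1
            per_diet.append(d)
        return shared, per_diet


def _effective_overrides(spec: DatasetSpec, freed: Dict[str, float]) -> Dict[str, float]:
    eff = dict(spec.overrides or {})
    eff.update(freed)
    return eff


def _simulate_problem(problem: FitProblem, shared: ParameterSet,
                      per_diet: List[Dict[str, float]]):
    """Simulate every dataset's protocol; returns per-dataset fraction
    tables and the total-iron (mg) at the adequate injection state."""
    # adequate reference condition: the first adequate-labeled dataset's
    # overrides, or the shared parameters as-is
    ade_over: Dict[str, float] = {}
    for spec, freed in zip(problem.datasets, per_diet):
        if spec.diet == "adequate":
            ade_over = _effective_overrides(spec, freed)
            break
    ade_params = shared.replace(**ade_over) if ade_over else shared
    plain = build_model(ade_params, include_tracer=False)
    cache = getattr(problem, "_ss_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(problem, "_ss_cache", cache)
    key = tuple(ade_params.to_dict().values())
    if key in cache:
        y_ade, total_fe = cache[key]
    else:
        y_ade = steady_state(plain, leadin_days=problem.leadin_days)
        total_fe = total_iron(y_ade, plain)
        if len(cache) > 64:
            cache.clear()
        cache[key] = (y_ade, total_fe)

    sims = []
    for spec, freed in zip(problem.datasets, per_diet):
        over = _effective_overrides(spec, freed)
        params_d = shared.replace(**over) if over else shared
        if spec.diet == "adequate":
            y_plain, model_d = y_ade, plain.with_params(params_d)
        else:
            model_d = build_model(params_d, include_tracer=False)
            y_plain = integrate(model_d.rhs, y_ade,
                                (0.0, problem.diet_leadin_days),
                                rtol=problem.sim_rtol, atol=1e-14)[-1]
        tracer = build_model(params_d, include_tracer=True)
        y0 = np.zeros(tracer.n_species)
        for i, s in enumerate(model_d.species):
            y0[tracer.index(s)] = y_plain[i]
        dose = default_dose(tracer, y0)
        y0 = inject_tracer(tracer, y0, dose)
        times = spec.dataset.times
        t_eval = times if times[0] == 0 else np.concatenate(([0.0], times))
        traj = run(tracer, y0, t_eval, rtol=problem.sim_rtol,
                   atol=tracer_atol(tracer, dose), injected_dose_mol=dose)
        sims.append(traj.tracer_fractions())
    return sims, total_fe


def objective(problem: FitProblem, theta_log: np.ndarray) -> Tuple[float, float]:
    """Sum of squared residuals and constraint violation at ``theta_log``.

    The violation is the squared distance (mg^2) of the adequate-diet
    total body iron from the allowed window; zero means feasible.
    Failed integrations return a large penalty so the search moves on.
    """
    shared, per_diet = problem.split(theta_log)
    try:
        sims, total_fe = _simulate_problem(problem, shared, per_diet)
    except (IntegrationError, FloatingPointError, ValueError) as exc:
        logger.debug("objective penalized: %s", exc)
        return PENALTY_SSQ, PENALTY_SSQ
    ssq = 0.0
    for spec, frac in zip(problem.datasets, sims):
        df = spec.dataset.df
        rows = frac.index.get_indexer(df["time_days"])
        cols = frac.columns.get_indexer(df["pool"])
        if np.any(rows < 0) or np.any(cols < 0):
            raise ValueError("dataset times/pools not aligned with simulation")
        sim = frac.to_numpy()[rows, cols]
        if not np.all(np.isfinite(sim)):
            return PENALTY_SSQ, PENALTY_SSQ
        r = sim - df["fraction_of_dose"].to_numpy()
        if problem.weighted:
            r = r / np.maximum(df["sd"].to_numpy(), 1e-12)
        ssq += float(r @ r)
    lo, hi = problem.constraint_mg
    viol = max(0.0, lo - total_fe) ** 2 + max(0.0, total_fe - hi) ** 2
    return float(ssq), float(viol)


# ---------------------------------------------------------------------------
# Fit results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """One calibrated model with recomputed derived quantities.

    Derived values (total iron, transferrin saturation, RBC transition
    time) are always recomputed from the returned parameters at the
    adequate-diet steady state, never cached from the search.
    """

    params: ParameterSet
    per_diet: List[Dict[str, float]]
    ssq: float
    constraint_violation: float
    feasible: bool
    total_fe_mg: float
    tf_saturation_pct: float
    rbc_transition_days: float
    optimizer: str
    seed: Optional[int]
    n_evals: int
    theta_names: Tuple[str, ...] = ()
    theta_log: Optional[np.ndarray] = None

    def to_dict(self) -> Dict:
        return {
            "params": self.params.to_dict(),
            "per_diet": self.per_diet,
            "ssq": self.ssq,
            "constraint_violation": self.constraint_violation,
            "feasible": self.feasible,
            "total_fe_mg": self.total_fe_mg,
            "tf_saturation_pct": self.tf_saturation_pct,
            "rbc_transition_days": self.rbc_transition_days,
            "optimizer": self.optimizer,
            "seed": self.seed,
            "n_evals": self.n_evals,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _derived(problem: FitProblem, shared: ParameterSet) -> Tuple[float, float, float]:
    """(TotalFe mg, Tf saturation %, RBC transition days) at steady state."""
    plain = build_model(shared, include_tracer=False)
    y = steady_state(plain, leadin_days=problem.leadin_days)
    content = compartment_iron_amount(plain, y, "rbc")
    outflow = compartment_iron_outflow(plain, y, "rbc")
    tau = content / outflow if outflow > 0 else math.inf
    return total_iron(y, plain), tf_saturation(y, plain), tau


def make_result(problem: FitProblem, theta_log: np.ndarray, ssq: float,
                viol: float, optimizer: str, seed: Optional[int],
                n_evals: int) -> FitResult:
    shared, per_diet = problem.split(theta_log)
    total_fe, tfsat, tau = _derived(problem, shared)
    lo, hi = problem.constraint_mg
    return FitResult(
        params=shared, per_diet=per_diet, ssq=float(ssq),
        constraint_violation=float(viol),
        feasible=bool(lo - 1e-9 <= total_fe <= hi + 1e-9),
        total_fe_mg=float(total_fe), tf_saturation_pct=float(tfsat),
        rbc_transition_days=float(tau), optimizer=optimizer, seed=seed,
        n_evals=n_evals, theta_names=problem.theta_names,
        theta_log=np.asarray(theta_log, dtype=float))


# ---------------------------------------------------------------------------
# SRES: evolution strategy with stochastic ranking
# ---------------------------------------------------------------------------

def _stochastic_rank(f: np.ndarray, phi: np.ndarray, pf: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Order individuals by stochastic ranking (bubble-sort formulation).

    Adjacent pairs are compared by the objective when both are feasible or
    with probability ``pf``; otherwise by constraint violation.  Balances
    objective descent against feasibility without penalty weights.
    """
    n = f.size
    order = np.arange(n)
    for _ in range(n):
        swapped = False
        u = rng.random(n - 1)
        for j in range(n - 1):
            a, b = order[j], order[j + 1]
            if (phi[a] == 0.0 and phi[b] == 0.0) or u[j] < pf:
                worse = f[a] > f[b]
            else:
                worse = phi[a] > phi[b]
            if worse:
                order[j], order[j + 1] = b, a
                swapped = True
        if not swapped:
            break
    return order


def sres_minimize(fun: Callable[[np.ndarray], Tuple[float, float]],
                  lb: np.ndarray, ub: np.ndarray, seed: int = 0,
                  lam: int = 200, mu: int = 30, generations: int = 250,
                  pf: float = 0.45) -> Tuple[np.ndarray, float, float, int]:
    """Core (mu, lambda) evolution strategy with stochastic ranking.

    ``fun`` returns (objective, constraint violation); violation 0 means
    feasible.  Self-adaptive log-normal step-size control; offspring
    outside the box bounds are reflected back in.  Returns the best
    feasible point encountered -- or, if none was ever feasible, the
    least-violating one -- as ``(x, f, violation, n_evals)``.  Fully
    reproducible under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    n = lb.size
    tau = 1.0 / math.sqrt(2.0 * math.sqrt(n))
    tau_prime = 1.0 / math.sqrt(2.0 * n)

    X = rng.uniform(lb, ub, size=(mu, n))
    S = np.tile((ub - lb) / math.sqrt(n), (mu, 1))

    best = None  # (f, viol, x)
    best_infeasible = None
    n_evals = 0

    def consider(f, phi, x):
        nonlocal best, best_infeasible
        if phi == 0.0:
            if best is None or f < best[0]:
                best = (f, phi, x.copy())
        elif best is None and (best_infeasible is None
                               or phi < best_infeasible[1]):
            best_infeasible = (f, phi, x.copy())

    for gen in range(generations):
        kids = np.empty((lam, n))
        sig = np.empty((lam, n))
        for k in range(lam):
            i = k % mu
            g = rng.standard_normal()
            sig[k] = S[i] * np.exp(tau_prime * g
                                   + tau * rng.standard_normal(n))
            x = X[i] + sig[k] * rng.standard_normal(n)
            # reflect into bounds
            x = np.where(x < lb, 2 * lb - x, x)
            x = np.where(x > ub, 2 * ub - x, x)
            kids[k] = np.clip(x, lb, ub)
        f = np.empty(lam)
        phi = np.empty(lam)
        for k in range(lam):
            f[k], phi[k] = fun(kids[k])
            n_evals += 1
            consider(f[k], phi[k], kids[k])
        order = _stochastic_rank(f, phi, pf, rng)[:mu]
        X, S = kids[order], sig[order]
        logger.debug("sres gen %d: best %s", gen, best[0] if best else None)

    if best is None:
        logger.warning("sres found no feasible individual; "
                       "returning least-violating point")
        return best_infeasible[2], best_infeasible[0], best_infeasible[1], n_evals
    return best[2], best[0], best[1], n_evals


def sres_optimize(problem: FitProblem, seed: int = 0, lam: int = 200,
                  mu: int = 30, generations: int = 250,
                  pf: float = 0.45) -> FitResult:
    """Constrained SRES fit of a :class:`FitProblem` (log10 search space)."""
    lb, ub = problem.log_bounds()
    x0, f0, phi0, n_evals = sres_minimize(
        lambda x: objective(problem, x), lb, ub, seed=seed, lam=lam, mu=mu,
        generations=generations, pf=pf)
    return make_result(problem, x0, f0, phi0, "SRES", seed, n_evals)


# ---------------------------------------------------------------------------
# Hooke--Jeeves local refinement
# ---------------------------------------------------------------------------

def _penalized(problem: FitProblem, x: np.ndarray) -> Tuple[float, float, float]:
    f, phi = objective(problem, x)
    return (f if phi == 0.0 else f + PENALTY_SSQ * (1.0 + phi)), f, phi


def hooke_jeeves(fun: Callable[[np.ndarray], float], x0: np.ndarray,
                 lb: np.ndarray, ub: np.ndarray, initial_step: float = 0.05,
                 step_tol: float = 1e-4, max_evals: int = 2000
                 ) -> Tuple[np.ndarray, float, int]:
    """Hooke--Jeeves pattern search (derivative-free local descent).

    Exploratory coordinate moves followed by pattern moves, halving the
    step on failure; the incumbent objective never increases.  Returns
    ``(x, f, n_evals)``.
    """
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    x = np.clip(np.asarray(x0, dtype=float), lb, ub)
    F = fun(x)
    n_evals = 1
    h = initial_step * np.ones_like(x)

    def explore(base, Fbase):
        nonlocal n_evals
        xb, Fb = base.copy(), Fbase
        for j in range(x.size):
            for sgn in (+1.0, -1.0):
                trial = xb.copy()
                trial[j] = np.clip(trial[j] + sgn * h[j], lb[j], ub[j])
                Ft = fun(trial)
                n_evals += 1
                if Ft < Fb:
                    xb, Fb = trial, Ft
                    break
        return xb, Fb

    while n_evals < max_evals and h.max() > step_tol:
        xn, Fn = explore(x, F)
        if Fn < F:
            # pattern move along the improvement direction
            while n_evals < max_evals:
                xp = np.clip(xn + (xn - x), lb, ub)
                x, F = xn, Fn
                xe, Fe = explore(xp, F)
                if Fe < F:
                    xn, Fn = xe, Fe
                else:
                    break
        else:
            h *= 0.5
    return x, F, n_evals


def local_refine(problem: FitProblem, start: FitResult,
                 initial_step: float = 0.05, step_tol: float = 1e-4,
                 max_evals: int = 2000) -> FitResult:
    """Refine a fit by Hooke--Jeeves on the penalized objective.

    Infeasibility is penalized heavily, so a feasible start stays feasible
    and its sum of squares can only improve.
    """
    lb, ub = problem.log_bounds()
    x, _, n_evals = hooke_jeeves(
        lambda z: _penalized(problem, z)[0],
        np.asarray(start.theta_log, dtype=float), lb, ub,
        initial_step=initial_step, step_tol=step_tol, max_evals=max_evals)
    f, phi = objective(problem, x)
    return make_result(problem, x, f, phi, start.optimizer + "+HJ",
                       start.seed, start.n_evals + n_evals)


# ---------------------------------------------------------------------------
# Ensembles, selection, comparison
# ---------------------------------------------------------------------------

def fit_ensemble(problem: FitProblem, seeds: Sequence[int],
                 refine: bool = True, **sres_kwargs
                 ) -> Tuple[List[FitResult], pd.Series]:
    """Independent fits from different seeds + per-parameter CV.

    The coefficient of variation (sd/mean across runs, in linear space)
    flags identifiable parameters: a small CV means independent searches
    keep landing on the same value.
    """
    if len(seeds) < 1:
        raise ValueError("at least one seed required")
    results = []
    for seed in seeds:
        res = sres_optimize(problem, seed=seed, **sres_kwargs)
        if refine:
            res = local_refine(problem, res)
        results.append(res)
    cv = ensemble_cv(results)
    return results, cv


def ensemble_cv(results: Sequence[FitResult]) -> pd.Series:
    names = results[0].theta_names
    vals = np.array([10.0 ** np.asarray(r.theta_log) for r in results])
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1) if len(results) > 1 else np.zeros_like(mean)
    return pd.Series(np.abs(sd / mean) * 100.0, index=list(names),
                     name="cv_percent")


def select_model(results: Sequence[FitResult],
                 target_transition_days: float = 40.0) -> FitResult:
    """Pick the feasible fit whose RBC transition time is nearest the mean
    erythrocyte lifetime (ties broken by lower sum of squares)."""
    feasible = [r for r in results if r.feasible]
    if not feasible:
        raise ValueError("no constraint-satisfying fit to select from")
    return min(feasible, key=lambda r: (abs(r.rbc_transition_days
                                            - target_transition_days), r.ssq))


def compare_params(ensemble_a: Sequence[FitResult],
                   ensemble_b: Sequence[FitResult]) -> pd.DataFrame:
    """Per-parameter Welch t-test on log10 values between two ensembles.

    Returns a table sorted by p-value; the most significant rows are the
    parameters the two conditions genuinely disagree on.  Identical
    zero-variance groups give t = 0, p = 1 by convention.
    """
    names_a = set(ensemble_a[0].theta_names)
    shared = [n for n in ensemble_a[0].theta_names
              if n in names_a & set(ensemble_b[0].theta_names)]
    rows = []
    for i, name in enumerate(shared):
        ia = ensemble_a[0].theta_names.index(name)
        ib = ensemble_b[0].theta_names.index(name)
        a = np.array([r.theta_log[ia] for r in ensemble_a])
        b = np.array([r.theta_log[ib] for r in ensemble_b])
        if a.std() == 0.0 and b.std() == 0.0:
            t, p = (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append((name, float(t), float(p),
                     float(10.0 ** a.mean()), float(10.0 ** b.mean())))
    df = pd.DataFrame(rows, columns=["parameter", "t", "p",
                                     "geomean_a", "geomean_b"])
    return df.sort_values("p", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Problem construction helpers
# ---------------------------------------------------------------------------

def default_bounds(base: ParameterSet, names: Iterable[str],
                   decades: float = 2.0) -> Dict[str, Tuple[float, float]]:
    """Log-symmetric box bounds around a reference parameter set."""
    return {n: (getattr(base, n) / 10 ** decades,
                getattr(base, n) * 10 ** decades) for n in names}


def adequate_fit_problem(dataset: TracerDataset, base: ParameterSet,
                         free: Sequence[str], decades: float = 2.0,
                         **kwargs) -> FitProblem:
    """Single-dataset adequate-diet problem with log-symmetric bounds."""
    return FitProblem(base=base, free=tuple(free),
                      bounds=default_bounds(base, free, decades),
                      datasets=[DatasetSpec(dataset, "adequate")], **kwargs)
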