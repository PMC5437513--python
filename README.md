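# ferrokin

Whole-body iron kinetics in the mouse: a compartmental ODE model with
radioactive-tracer bookkeeping, hepcidin-regulated ferroportin export,
constrained parameter estimation, and diet/disease simulation protocols.

## What this is for

Systemic iron homeostasis is controlled by the hormone hepcidin, which
degrades ferroportin — the only cellular iron exporter — and thereby traps
iron in tissues. `ferrokin` is for quantitatively testing that regulation:
it simulates the distribution of a small injected radio-iron dose across
plasma, duodenum, bone marrow, red blood cells, liver, spleen, the rest of
the body and the excreted fraction, and calibrates the model against such
tracer time courses under different dietary regimes. It is aimed at
systems physiologists who want a tested, scriptable reimplementation of
this model class rather than a GUI simulator session.

The model couples, per compartment, ODEs for labeled and unlabeled iron
sharing all rate constants. Tissue iron export follows

```
v = V · Volume · [S] / ( (Km + [S] + [Ic]) · (1 + [Hep]/Ki) )
```

— saturable ferroportin kinetics with the isotopic twin `[Ic]` as a
competitive inhibitor and hepcidin as a non-competitive inhibitor (an
apparent-Vmax effect, matching hepcidin's degradation of the
transporter). Transferrin loading is irreversible mass action over all
isotope combinations; tissue uptake, erythroid maturation/recycling and
iron loss are first order; the diet is a constant duodenal influx.
Calibration minimizes the sum of squared residuals on fraction-of-dose
observables under the physiological constraint 1.8 mg ≤ total body iron ≤
2.2 mg, using an evolution strategy with stochastic ranking (SRES) plus
Hooke–Jeeves refinement, in log10 parameter space. See
[docs/methods.md](docs/methods.md) for the full account.

## Worked example

```python
import ferrokin as fk
from ferrokin.protocols import tracer_experiment, transition_time
from ferrokin.pipeline import diet_characteristics, run_anemia

params = fk.fixture_table2(6)          # canonical adequate-diet estimate

print(diet_characteristics(params, duration_days=0.0))
# {'tf_saturation_pct': 46.73, 'total_iron_mg': 2.2,
#  'hepcidin_nM': 23.0, 'ntbi_nM': 33.1, 'excretion_ug_per_day': 8.2}

print(transition_time(params, "rbc"))  # 42.55  (days)
```

The first call equilibrates the tracer-free model and reports the
adequate-diet steady state: 2.2 mg total body iron at 47% transferrin
saturation, 33 nM plasma NTBI and 23 nM hepcidin. The transition time —
steady-state RBC iron content divided by its outflow flux — is 42.55
days, the mean residence time of iron in the red cells, close to the
~40-day erythrocyte lifetime in mice (this is why estimate #6 of the
published ensemble is the canonical one).

A tracer experiment and a disease simulation:

```python
import numpy as np
traj = tracer_experiment(params,
                         observation_days=np.geomspace(1e-3, 28, 400))
frac = traj.tracer_fractions()
print(f"{100 * frac['bone_marrow'].max():.1f}")   # 54.6  (% of dose, BM peak)
print(f"{100 * frac['rbc'].iloc[-1]:.1f}")        # 63.3  (% of dose in RBC, day 28)

study = run_anemia(params, hepcidin_fold=5.0)     # a year at 5x hepcidin
print({k: round(v, 2) for k, v in study.report.fold_changes.items()})
# {'plasma': 0.32, 'duodenum': 7.22, 'bone_marrow': 0.32, 'rbc': 0.34,
#  'liver': 1.98, 'spleen': 1.98, 'rest': 0.59, 'total': 0.57}
```

The injected label clears the plasma within hours, peaks in the bone
marrow at ~55% of dose around day 0.13, and accumulates in the red cells
(~63% plateau). Raising hepcidin five-fold for a year reproduces the
anemia-of-chronic-disease signature: plasma, marrow and RBC iron fall
~3-fold, total iron halves, while the duodenum (7-fold), liver and spleen
(2-fold each) accumulate iron — the spleen with an early overshoot near
day 30, the liver peaking around day 160.

Synthetic tracer data and calibration:

```python
ds = fk.generate(params, noise_cv=0.05, seed=42)      # 96 records, 8 pools
problem = fk.adequate_fit_problem(ds, params, free=("kInRBC", "kRestOut"))
fit = fk.local_refine(problem, fk.sres_optimize(problem, seed=1,
                                                lam=40, mu=6, generations=30))
print(fit.feasible, fit.total_fe_mg, fit.rbc_transition_days)
```

Every returned feasible fit has its total body iron recomputed at its own
steady state inside the 2 ± 0.2 mg window; on synthetic data the sharply
identifiable constants (`kInRBC`, `kRestOut`) come back within a few
percent of the generating truth, while loosely identified ones (the
ferroportin Vmax values) roam — mirroring the identifiability structure
of the published ensemble.

There is also a CLI (`ferrokin generate-data|simulate|steady-state|fit|
refit-diet|joint-fit|anemia|diet-table|compare-params|export-sbml`), and
models can be exported as SBML Level 3 for exchange with other
simulators.

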