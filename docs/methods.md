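# Methods

## The model

`ferrokin` implements a whole-body compartmental model of iron
distribution in the mouse. Seven body compartments carry iron pools —
plasma, duodenum, bone marrow, red blood cells (RBC), liver, spleen and a
lumped "rest of body" — plus an "outside" sink that accumulates excreted
iron. Apart from the plasma, each compartment holds a single iron species;
the plasma resolves non-transferrin-bound iron (NTBI), apo-transferrin
(Tf), mono- and di-ferric transferrin (Fe1Tf, Fe2Tf) and hepcidin. Every
iron species has a radioactive twin (`*`) governed by the same rate
constants (kinetic isotope effects are neglected), so that a small ⁵⁹Fe-like
dose injected into plasma NTBI can be tracked as a *fraction of injected
dose* per compartment — the observable of a classical ferrokinetic
experiment. Di-ferric transferrin exists in three isotopic forms
(Fe2Tf, Fe2Tf\*, Fe2Tf\*\*), so the tracer model has 23 species and 47
reactions; the tracer-free reduction has 12 species and 22 reactions.

Processes and rate laws:

* **Ferroportin export** from duodenum, liver, spleen and rest into plasma
  NTBI follows saturable kinetics with isotopic competition and
  non-competitive inhibition by hepcidin:

  `v = V · Volume · [S] / ((Km + [S] + [Ic]) · (1 + [Hep]/Ki))`

  `[S]` is the exported species, `[Ic]` its isotopic twin (both compete
  for the same transporter, with identical affinity), and the hepcidin
  term lowers the apparent Vmax — matching hepcidin's mode of action,
  which is degradation of the transporter itself. `Km` and `Ki` are
  shared by all four export reactions (properties of the protein); the
  limiting rate `V` is organ-specific (it reflects the ferroportin level
  of the tissue).
* **Transferrin loading**: NTBI (+ NTBI\*) binds Tf and Fe1Tf by
  irreversible second-order mass action (all six isotope combinations,
  one shared constant per step). Irreversibility reflects the ~1e-22 M
  dissociation constant of ferric transferrin.
* **Tissue uptake**: bone marrow, liver, duodenum and rest import iron
  from Fe1Tf/Fe2Tf (all isotopic forms, one first-order constant per
  organ); Tf returns to the plasma, di-ferric forms deliver two iron ions
  (the mixed form one of each isotope). RBC acquire no iron from plasma.
* **Erythroid dynamics**: marrow→RBC maturation (`kInRBC`), direct
  marrow→spleen recycling of premature cells (`kBMSpleen`), and
  RBC→spleen macrophage recycling (`vRBCSpleen`), all first order.
* **Diet and loss**: a constant influx `vDiet·V_duo` into the duodenum
  (the time-averaged dietary import; no discrete meals) and first-order
  losses duodenum→outside (enterocyte sloughing) and rest→outside
  (skin/hair shedding). The diet carries no label.
* **Hepcidin**: constant synthesis (`kHepSyn`), first-order degradation
  (`kHepDeg`); no feedback from the iron state. Diet and disease
  protocols act on `kHepSyn` only.

Rates are extensive (mol/day) because reactions cross compartments of
different volume; each concentration ODE divides the signed flux sum by
its compartment volume, and the outside pools are integrated in amount
(mol). Volumes are fixed (Compartment defaults, in liters, derived from
mouse organ masses and reference organ densities).

Conserved quantities, used as integration checks: total transferrin
(3.87e-5 M), total labeled iron after injection, and
d(total iron incl. outside)/dt = `vDiet·V_duo` exactly.

## Parameters and units

The 17 kinetic constants of the canonical adequate-diet parameterization
(`fixture_table2(6)`) come from a published ensemble of ten independent
constrained fits; column 6 is canonical because its RBC transition time
(42.5 d) matches the mean erythrocyte lifetime in mice (~40 d) and its
transferrin saturation (47%) is physiological. Units: first-order
constants 1/day; ferroportin limiting rates in M/day (multiplied by the
source volume in the rate law — the dimensionally consistent reading of
the published table, whose header prints mol/day); `vDiet` in M/day
applied over the duodenal volume; binding constants in 1/(M·day).
Fraction-of-dose observables are invariant to both unit conventions.

Three hepcidin constants close the model but are not identifiable from
tracer fractions and were never published:

* `kHepDeg = 1/day`, `kHepSyn = 2.3e-8 M/day`, giving a 23 nM steady
  hormone level (the reported adequate-diet value).
* `Ki` (the non-competitive inhibition constant) is **calibrated** by a
  scalar solve so that the canonical model's adequate-diet steady state
  carries the reported 2.2 mg of total body iron
  (`protocols.fit_hepcidin_ki`; frozen default 9.7318e-10 M). This choice
  is strongly corroborated: with it, the steady state lands on ~47%
  transferrin saturation and ~33 nM NTBI — the other two reported
  characteristics — without further adjustment. A weak-inhibition choice
  (e.g. Ki ≈ the circulating 23 nM level) is *inconsistent* with the
  published steady state: export then outruns the loss pathways, the
  body cannot excrete the dietary influx, and total iron grows without
  bound. Exact deposited values can replace the defaults via
  `io.read_params_from_sbml` on the archived model files
  (`synthetic.BIOMODELS_ACCESSIONS`).

## Protocols

* **Equilibration**: a 5000-day lead-in brings the tracer-free system to
  its quasi steady state (`quasi_steady_state`); `steady_state` polishes
  the lead-in endpoint with a root solve (excreted pools, which grow
  secularly, are excluded from the root condition). Residual relative
  derivative norms are logged.
* **Tracer pulse**: the dose defaults to 1e-7 of the plasma iron amount —
  deep inside the linear regime, so fraction-of-dose curves are
  dose-invariant to ~1e-6 relative. (A dose of 1e-4 of plasma iron
  already perturbs apo-transferrin measurably, ~3e-4 relative.) Labeled
  species get dose-scaled absolute tolerances; the default integrator is
  LSODA at rtol 1e-10.
* **Diet switch** (`apply_diet`): exactly two parameters may change —
  `vDiet` and `kHepSyn`; anything else is rejected. Experimental diets
  run 35 days ("5 weeks") before the pulse, so diet datasets reflect a
  transient, not the new diet's steady state.
* **Observation grid**: {0.01, 0.04, 0.17, 0.5, 1, 2, 4, 7, 10, 14, 21,
  28} days — dense over the fast plasma-clearance phase (label leaves
  plasma at ~25/day, the summed tissue import rate), sparse over the slow
  RBC phase. The source experiment's actual sampling times are not
  printed; this grid spans both phases.
* **Anemia of chronic disease**: from the adequate steady state,
  `kHepSyn` is scaled five-fold and the system is run for 365 days;
  per-pool fold changes, peak values and peak times are reported.
* **Transition time**: steady-state pool content divided by outflow flux,
  computed by reaction-level bookkeeping; for the RBC pool (single
  first-order exit) it reduces to `1/vRBCSpleen`.

## Calibration

The objective is the unweighted sum of squared residuals between
simulated and observed fraction-of-dose values over all times and pools
(optionally 1/sd²-weighted when the dataset carries uncertainties), with
the nonlinear constraint 1.8 mg ≤ TotalFe ≤ 2.2 mg evaluated at the state
that starts the tracer phase. Search runs in log10 space (constants span
ten orders of magnitude).

* **SRES** (`sres_minimize`): a (μ,λ) evolution strategy with stochastic
  ranking — adjacent individuals are compared by objective when both are
  feasible or with probability Pf=0.45, otherwise by constraint
  violation. Self-adaptive log-normal step sizes, bound reflection,
  best-feasible elitism. Library defaults λ=200, μ=30, 250 generations;
  the test suite uses reduced budgets (λ=16–60, 8–60 generations over
  2–5 free parameters), which at this problem size recover the
  identifiable constants to a few percent in tens of seconds.
* **Local refinement**: Hooke–Jeeves pattern search on a penalized
  objective; monotone, so refinement never worsens a feasible fit. The
  two-parameter diet refit is additionally refined from the one-parameter
  solution, making the nested-model inequality hold by construction.
* **Ensembles**: independent seeds; per-parameter coefficient of
  variation across runs flags identifiability (kRestOut and kInRBC are
  sharp, ~1–5%; several ferroportin Vmax values are loose, >150%).
  Model selection takes the feasible fit whose RBC transition time is
  closest to 40 days (ties: lower SSQ).
* **Between-condition comparison**: Welch's two-sample t-test per shared
  parameter on log10 values (the published analysis says "pair-wise
  t-test" without specifying the flavor; unequal-variance two-sample on
  log parameters is the robust default for positive, log-searched
  constants).
* Failed or budget-exceeding integrations (pathological candidates can
  be arbitrarily stiff; each integration is capped at 150k RHS
  evaluations) are penalized with a large objective value.

Joint fits share all parameters across diets except per-diet
(`vDiet`, `kHepSyn`); freeing any other parameter per-diet is rejected.
Note that `vDiet` is nearly unidentifiable from a 5-week switch
experiment (the objective is flat across more than a decade), which is
why the adequate-diet fits fix it at the literature turnover value.

## Synthetic data

The generator reproduces the structure of the radio-iron experiment the
model was originally calibrated on: lead-in, optional 5-week diet switch,
tracer pulse, sampling of the 8 reported pools on the observation grid,
and multiplicative Gaussian noise with a chosen coefficient of variation
(default 5%), truncated at zero, with per-point sd = cv × mean recorded.
Diet scenarios default to (vDiet×0.25, kHepSyn×0.5) for deficient and
(vDiet×4, kHepSyn×1.35) for rich — illustrative stand-ins, chosen so the
steady hormone levels land at the reported 11 nM and 31 nM; the actual
refitted values live only in the deposited model files. What the
generator does *not* emulate: animal-to-animal variability and pooling,
the real (unpublished) sampling times and per-point standard deviations,
and any intracellular iron heterogeneity. Passing recovery tests
therefore demonstrate estimator correctness under the model's own noise
assumptions, not robustness to real biological variation.

## Numerical choices

* LSODA throughout (the system is stiff: binding at ~1e9/(M·day) against
  turnover at ~0.02/day); rtol 1e-10/atol 1e-14 for reported
  trajectories, rtol 1e-8 inside fitting objectives, rtol 1e-6 +
  root-polish for lead-ins.
* Trajectories are clipped at zero after integration; dips below −1e-8
  are logged loudly (none occur at the default tolerances).
* The compiled right-hand side (numba) is cross-checked against a
  reaction-by-reaction reference evaluation in the test suite.
* Degenerate inputs: zero-length time spans echo the initial state; a
  zero-throughput pool makes the transition time undefined (raised);
  zero-variance identical ensembles give t=0, p=1 in comparisons.

## Known limitations

* Single iron pool per tissue: no ferritin/heme/labile subpools, no
  TfR1/TfR2 saturation, no IRE/IRP regulation. Consequently the model
  cannot reproduce preferential liver loading when hepcidin is suppressed
  (hemochromatosis); `pipeline.hemochromatosis_check` makes this
  *expected* failure inspectable.
* Hepcidin has no feedback from iron status; diets and disease are
  modeled as parameter changes.
* Under a rich diet the hepcidin-only regulation over-predicts RBC and
  under-predicts liver tracer when the underlying truth changes liver
  uptake — the characteristic misfit pattern the acceptance suite
  checks.
* The bone-marrow peak tracer fraction computes to ~55% of dose (import
  share 63%, attenuated by marrow turnover during uptake), with the RBC
  plateau at ~63%; verbal reports of "60%" for this experiment sit
  between the two readings.
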