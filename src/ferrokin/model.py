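"""Whole-body mouse iron distribution model.

Compartmental ODE system for iron exchange between plasma, duodenum, bone
marrow, red blood cells, liver, spleen and the rest of the body, with an
"outside" sink for excreted iron.  Each tissue holds one iron pool; the
plasma additionally carries non-transferrin-bound iron (NTBI), apo- and
mono-/di-ferric transferrin, and hepcidin.  Every iron species has a
radioactive twin (suffix ``*``) sharing all rate constants, so a small
labeled dose injected into plasma NTBI can be followed as a fraction of
dose per compartment, mirroring a classical ferrokinetic experiment.

Kinetics
--------
* Ferroportin export (duodenum, liver, spleen, rest -> plasma NTBI) is
  saturable with the unlabeled/labeled twin acting as a competitive
  inhibitor and hepcidin as a non-competitive inhibitor:

      v = V * Volume * [S] / ((Km + [S] + [Ic]) * (1 + [Hep]/Ki))

* Transferrin loading (NTBI + Tf -> Fe1Tf, NTBI + Fe1Tf -> Fe2Tf and all
  label combinations) is irreversible mass action (the Fe-Tf Kd is ~1e-22 M,
  so release is negligible on these timescales).
* Tissue iron uptake from Fe1Tf/Fe2Tf, erythroid maturation (bone marrow ->
  RBC, bone marrow -> spleen, RBC -> spleen) and iron loss (duodenum/rest ->
  outside) are irreversible first order.
* Dietary iron enters the duodenum at a constant rate; hepcidin is produced
  at a constant rate and degraded first order.

All reaction rates are extensive (mol/day) because reactions cross
compartments of different volume; concentration ODEs divide by the species'
home-compartment volume.  The outside pools are tracked in amount (mol).
"""

from __future__ import annotations

import logging
import math
from dataclasses import MISSING, dataclass, field, fields, replace as _dc_replace
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
from numba import njit

logger = logging.getLogger("ferrokin")

# ---------------------------------------------------------------------------
# Constants and compartments
# ---------------------------------------------------------------------------

IRON_MOLAR_MASS = 55.845  # g/mol

#: body compartment volumes in liters (mouse organ masses / human organ
#: densities; "outside" carries no volume-dependent kinetics)
DEFAULT_VOLUMES: Dict[str, float] = {
    "bone_marrow": 2.1e-4,
    "duodenum": 3.9e-5,
    "liver": 1.2e-3,
    "plasma": 1.3e-3,
    "rbc": 7.9e-4,
    "rest": 2.0e-2,
    "spleen": 6.7e-5,
}

COMPARTMENT_NAMES = tuple(DEFAULT_VOLUMES) + ("outside",)


class ConfigurationError(ValueError):
    """Raised when a model is assembled from an invalid configuration."""


@dataclass(frozen=True)
class Compartment:
    """A body compartment with a fixed aqueous volume in liters."""

    name: str
    volume: float

    def __post_init__(self):
        if self.name not in COMPARTMENT_NAMES:
            raise ConfigurationError(f"unknown compartment {self.name!r}")
        if self.name != "outside" and not self.volume > 0:
            raise ConfigurationError(f"compartment {self.name!r} needs volume > 0")


def default_compartments() -> Dict[str, Compartment]:
    comps = {n: Compartment(n, v) for n, v in DEFAULT_VOLUMES.items()}
    comps["outside"] = Compartment("outside", 0.0)
    return comps


# ---------------------------------------------------------------------------
# Species bookkeeping
# ---------------------------------------------------------------------------

#: full species list of the tracer model, in ODE state-vector order.
#: Names follow the field convention: '*' marks the radioactive twin.
SPECIES: Tuple[str, ...] = (
    "FeBM", "FeBM*",
    "FeDuo", "FeDuo*",
    "FeLiver", "FeLiver*",
    "FeSpleen", "FeSpleen*",
    "FeRBC", "FeRBC*",
    "FeRest", "FeRest*",
    "NTBI", "NTBI*",
    "Tf",
    "Fe1Tf", "Fe1Tf*",
    "Fe2Tf", "Fe2Tf*", "Fe2Tf**",
    "Hepcidin",
    "FeOutside", "FeOutside*",
)

#: species of the tracer-free model, in state-vector order
PLAIN_SPECIES: Tuple[str, ...] = (
    "FeBM", "FeDuo", "FeLiver", "FeSpleen", "FeRBC", "FeRest",
    "NTBI", "Tf", "Fe1Tf", "Fe2Tf", "Hepcidin", "FeOutside",
)

SPECIES_COMPARTMENT: Dict[str, str] = {
    "FeBM": "bone_marrow", "FeBM*": "bone_marrow",
    "FeDuo": "duodenum", "FeDuo*": "duodenum",
    "FeLiver": "liver", "FeLiver*": "liver",
    "FeSpleen": "spleen", "FeSpleen*": "spleen",
    "FeRBC": "rbc", "FeRBC*": "rbc",
    "FeRest": "rest", "FeRest*": "rest",
    "NTBI": "plasma", "NTBI*": "plasma",
    "Tf": "plasma",
    "Fe1Tf": "plasma", "Fe1Tf*": "plasma",
    "Fe2Tf": "plasma", "Fe2Tf*": "plasma", "Fe2Tf**": "plasma",
    "Hepcidin": "plasma",
    "FeOutside": "outside", "FeOutside*": "outside",
}

#: iron atoms carried per molecule of each species (label-blind)
IRON_CONTENT: Dict[str, int] = {
    **{s: 1 for s in SPECIES},
    "Tf": 0, "Hepcidin": 0,
    "Fe2Tf": 2, "Fe2Tf*": 2, "Fe2Tf**": 2,
}

#: radioactive iron atoms carried per molecule
LABEL_CONTENT: Dict[str, int] = {
    s: (1 if s.endswith("*") else 0) for s in SPECIES
}
LABEL_CONTENT["Fe2Tf*"] = 1
LABEL_CONTENT["Fe2Tf**"] = 2

#: the label-swap involution: exchanging every labeled/unlabeled twin
LABEL_SWAP: Dict[str, str] = {}
for _s in SPECIES:
    if _s == "Fe2Tf*":
        LABEL_SWAP[_s] = _s  # one of each isotope: self-symmetric
    elif _s == "Fe2Tf":
        LABEL_SWAP[_s] = "Fe2Tf**"
    elif _s == "Fe2Tf**":
        LABEL_SWAP[_s] = "Fe2Tf"
    elif _s.endswith("*"):
        LABEL_SWAP[_s] = _s[:-1]
    elif _s + "*" in SPECIES:
        LABEL_SWAP[_s] = _s + "*"
    else:
        LABEL_SWAP[_s] = _s  # Tf, Hepcidin


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

#: hepcidin non-competitive inhibition constant (M).  Chosen so that the
#: canonical adequate-diet parameterization reaches its reported steady
#: state of 2.2 mg total body iron at the 23 nM circulating hepcidin
#: level (see protocols.fit_hepcidin_ki, which re-derives this value);
#: the resulting state also lands on the reported ~47% transferrin
#: saturation and ~33 nM plasma NTBI without further adjustment.
DEFAULT_KI = 9.7318e-10

#: hepcidin turnover: first-order degradation at 1/day and constant
#: synthesis giving a 23 nM steady-state level under the adequate diet.
DEFAULT_KHEPDEG = 1.0
DEFAULT_KHEPSYN = 2.3e-8

DEFAULT_TFTOTAL = 3.87e-5  # M, total plasma transferrin


@dataclass
class ParameterSet:
    """Kinetic constants of the iron distribution model.

    First-order constants are in 1/day, ferroportin limiting rates ``V*``
    in M/day (multiplied by the source-compartment volume in the rate law
    to give mol/day), ``Km``/``Ki`` in M, ``vDiet``/``kHepSyn`` in M/day,
    binding constants in 1/(M day).
    """

    kInDuo: float
    kInLiver: float
    kInRBC: float
    kInRest: float
    kInBM: float
    kDuoLoss: float
    kRestOut: float
    kBMSpleen: float
    VDuoNTBI: float
    VLiverNTBI: float
    VSpleenNTBI: float
    VRestNTBI: float
    vRBCSpleen: float
    Km: float
    vDiet: float
    kNTBI_Fe1Tf: float
    kFe1Tf_Fe2Tf: float
    Ki: float = DEFAULT_KI
    kHepSyn: float = DEFAULT_KHEPSYN
    kHepDeg: float = DEFAULT_KHEPDEG
    TfTotal: float = DEFAULT_TFTOTAL

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                raise ConfigurationError(f"missing parameter {f.name!r}")
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ConfigurationError(
                    f"parameter {f.name!r} must be a positive finite number, got {v!r}"
                )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> Dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Dict[str, float]) -> "ParameterSet":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown parameter(s): {sorted(unknown)}")
        required = {f.name for f in fields(cls)
                    if f.default is MISSING and f.default_factory is MISSING}
        missing = required - set(d)
        if missing:
            raise ConfigurationError(f"missing parameter(s): {sorted(missing)}")
        return cls(**d)

    def replace(self, **updates: float) -> "ParameterSet":
        known = {f.name for f in fields(self)}
        unknown = set(updates) - known
        if unknown:
            raise ConfigurationError(f"unknown parameter(s): {sorted(unknown)}")
        return _dc_replace(self, **updates)

    names = classmethod(lambda cls: tuple(f.name for f in fields(cls)))


#: packing order of the parameter vector consumed by the compiled RHS
_PACK_ORDER = (
    "kInDuo", "kInLiver", "kInRBC", "kInRest", "kInBM",
    "kDuoLoss", "kRestOut", "kBMSpleen",
    "VDuoNTBI", "VLiverNTBI", "VSpleenNTBI", "VRestNTBI",
    "vRBCSpleen", "Km", "vDiet", "kNTBI_Fe1Tf", "kFe1Tf_Fe2Tf",
    "Ki", "kHepSyn", "kHepDeg",
)

_VOL_ORDER = ("bone_marrow", "duodenum", "liver", "plasma", "rbc", "rest", "spleen")


def pack_params(params: ParameterSet) -> np.ndarray:
    return np.array([getattr(params, n) for n in _PACK_ORDER], dtype=float)


def pack_volumes(compartments: Dict[str, Compartment]) -> np.ndarray:
    return np.array([compartments[n].volume for n in _VOL_ORDER], dtype=float)


# ---------------------------------------------------------------------------
# Elementary rate laws
# ---------------------------------------------------------------------------

def ferroportin_rate(S: float, Ic: float, Hep: float, V: float, Km: float,
                     Ki: float, volume: float) -> float:
    """Saturable ferroportin export flux in mol/day.

    ``S`` is the exported iron species, ``Ic`` its isotopic twin competing
    for the transporter, ``Hep`` the hepcidin concentration acting as a
    non-competitive inhibitor (hepcidin degrades ferroportin, lowering the
    apparent Vmax).  ``V`` is the limiting rate (M/day) and ``volume`` the
    source-compartment volume (L).
    """
    return V * volume * S / ((Km + S + Ic) * (1.0 + Hep / Ki))


def mass_action_flux(k: float, S: float, source_volume: float) -> float:
    """First-order flux k*[S]*V in mol/day (extensive units)."""
    return k * S * source_volume


def tf_binding_flux(k: float, ntbi_like: float, tf_like: float,
                    plasma_volume: float) -> float:
    """Irreversible second-order transferrin iron-loading flux in mol/day."""
    return k * ntbi_like * tf_like * plasma_volume


# ---------------------------------------------------------------------------
# Reaction network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    """One reaction of the network.

    ``stoich`` maps species to signed net stoichiometry.  ``kind`` selects
    the rate law; ``rate_params`` maps rate-law slots to ParameterSet field
    names; ``substrates`` are the species whose concentrations enter the
    rate; ``compartment`` supplies the volume factor of the extensive rate.
    """

    name: str
    kind: str  # constant_flux | mass_action | mass_action_2 | ferroportin | synthesis | decay
    stoich: Dict[str, int]
    rate_params: Dict[str, str]
    substrates: Tuple[str, ...]
    compartment: str
    inhibitor: Optional[str] = None  # competitive twin (ferroportin only)


#: transferrin-mediated import targets: organ key -> (rate constant, pool)
_IMPORT_ORGANS = (
    ("duodenum", "kInDuo", "FeDuo"),
    ("liver", "kInLiver", "FeLiver"),
    ("rest", "kInRest", "FeRest"),
    ("bone_marrow", "kInBM", "FeBM"),
)

_FPN_ORGANS = (
    ("duodenum", "VDuoNTBI", "FeDuo"),
    ("liver", "VLiverNTBI", "FeLiver"),
    ("spleen", "VSpleenNTBI", "FeSpleen"),
    ("rest", "VRestNTBI", "FeRest"),
)


def _build_reactions(include_tracer: bool) -> Tuple[Reaction, ...]:
    rxns = []
    labels = ("", "*") if include_tracer else ("",)

    # dietary influx (unlabeled only: the diet carries no tracer)
    rxns.append(Reaction("diet_influx", "constant_flux", {"FeDuo": +1},
                         {"v": "vDiet"}, (), "duodenum"))

    # ferroportin export to plasma NTBI, each label competing with its twin
    for comp, vname, pool in _FPN_ORGANS:
        for lab in labels:
            s = pool + lab
            twin = pool + ("*" if lab == "" else "")
            rxns.append(Reaction(
                f"fpn_{pool}{lab}", "ferroportin",
                {s: -1, "NTBI" + lab: +1},
                {"V": vname, "Km": "Km", "Ki": "Ki"},
                (s,), comp,
                inhibitor=twin if include_tracer else None))

    # transferrin iron loading (all isotope combinations)
    def _bind(name, k, a, b, prod):
        rxns.append(Reaction(name, "mass_action_2",
                             {a: -1, b: -1, prod: +1},
                             {"k": k}, (a, b), "plasma"))

    for lab in labels:
        _bind(f"bind_NTBI{lab}_Tf", "kNTBI_Fe1Tf", "NTBI" + lab, "Tf", "Fe1Tf" + lab)
    _bind("bind_NTBI_Fe1Tf", "kFe1Tf_Fe2Tf", "NTBI", "Fe1Tf", "Fe2Tf")
    if include_tracer:
        _bind("bind_NTBI_Fe1Tf*", "kFe1Tf_Fe2Tf", "NTBI", "Fe1Tf*", "Fe2Tf*")
        _bind("bind_NTBI*_Fe1Tf", "kFe1Tf_Fe2Tf", "NTBI*", "Fe1Tf", "Fe2Tf*")
        _bind("bind_NTBI*_Fe1Tf*", "kFe1Tf_Fe2Tf", "NTBI*", "Fe1Tf*", "Fe2Tf**")

    # transferrin-mediated iron import; Tf returns to plasma.  One rate
    # constant per organ serves every transferrin form; di-ferric forms
    # deliver two iron ions (the mixed form one of each isotope).
    for comp, kname, pool in _IMPORT_ORGANS:
        rxns.append(Reaction(f"import_Fe1Tf_{pool}", "mass_action",
                             {"Fe1Tf": -1, "Tf": +1, pool: +1},
                             {"k": kname}, ("Fe1Tf",), "plasma"))
        rxns.append(Reaction(f"import_Fe2Tf_{pool}", "mass_action",
                             {"Fe2Tf": -1, "Tf": +1, pool: +2},
                             {"k": kname}, ("Fe2Tf",), "plasma"))
        if include_tracer:
            rxns.append(Reaction(f"import_Fe1Tf*_{pool}", "mass_action",
                                 {"Fe1Tf*": -1, "Tf": +1, pool + "*": +1},
                                 {"k": kname}, ("Fe1Tf*",), "plasma"))
            rxns.append(Reaction(f"import_Fe2Tf*_{pool}", "mass_action",
                                 {"Fe2Tf*": -1, "Tf": +1, pool: +1, pool + "*": +1},
                                 {"k": kname}, ("Fe2Tf*",), "plasma"))
            rxns.append(Reaction(f"import_Fe2Tf**_{pool}", "mass_action",
                                 {"Fe2Tf**": -1, "Tf": +1, pool + "*": +2},
                                 {"k": kname}, ("Fe2Tf**",), "plasma"))

    # erythroid dynamics: maturation and macrophage recycling.  RBC acquire
    # iron exclusively in the bone marrow -- there is no direct import of
    # plasma iron into circulating erythrocytes.
    for lab in labels:
        rxns.append(Reaction(f"bm_to_rbc{lab}", "mass_action",
                             {"FeBM" + lab: -1, "FeRBC" + lab: +1},
                             {"k": "kInRBC"}, ("FeBM" + lab,), "bone_marrow"))
        rxns.append(Reaction(f"bm_to_spleen{lab}", "mass_action",
                             {"FeBM" + lab: -1, "FeSpleen" + lab: +1},
                             {"k": "kBMSpleen"}, ("FeBM" + lab,), "bone_marrow"))
        rxns.append(Reaction(f"rbc_to_spleen{lab}", "mass_action",
                             {"FeRBC" + lab: -1, "FeSpleen" + lab: +1},
                             {"k": "vRBCSpleen"}, ("FeRBC" + lab,), "rbc"))
        # iron loss: enterocyte sloughing and skin/hair shedding
        rxns.append(Reaction(f"duo_loss{lab}", "mass_action",
                             {"FeDuo" + lab: -1, "FeOutside" + lab: +1},
                             {"k": "kDuoLoss"}, ("FeDuo" + lab,), "duodenum"))
        rxns.append(Reaction(f"rest_loss{lab}", "mass_action",
                             {"FeRest" + lab: -1, "FeOutside" + lab: +1},
                             {"k": "kRestOut"}, ("FeRest" + lab,), "rest"))

    # hepcidin turnover (no tracer twin; unaffected by iron state)
    rxns.append(Reaction("hepcidin_synthesis", "synthesis", {"Hepcidin": +1},
                         {"v": "kHepSyn"}, (), "plasma"))
    rxns.append(Reaction("hepcidin_degradation", "decay", {"Hepcidin": -1},
                         {"k": "kHepDeg"}, ("Hepcidin",), "plasma"))
    return tuple(rxns)


@dataclass
class ModelSpec:
    """Assembled reaction network plus parameter/compartment bindings."""

    params: ParameterSet
    include_tracer: bool
    compartments: Dict[str, Compartment] = field(default_factory=default_compartments)
    species: Tuple[str, ...] = ()
    reactions: Tuple[Reaction, ...] = ()

    def __post_init__(self):
        if not self.species:
            self.species = SPECIES if self.include_tracer else PLAIN_SPECIES
        if not self.reactions:
            self.reactions = _build_reactions(self.include_tracer)
        self._index = {s: i for i, s in enumerate(self.species)}
        self._check_bindings()
        self._p = pack_params(self.params)
        self._vols = pack_volumes(self.compartments)

    # -- plumbing ----------------------------------------------------------
    def _check_bindings(self) -> None:
        valid = set(ParameterSet.names())
        for r in self.reactions:
            for slot, pname in r.rate_params.items():
                if pname not in valid:
                    raise ConfigurationError(
                        f"reaction {r.name!r}: unbound parameter {pname!r}")
            for s in r.stoich:
                if s not in self._index:
                    raise ConfigurationError(
                        f"reaction {r.name!r}: unknown species {s!r}")

    def index(self, species: str) -> int:
        return self._index[species]

    @property
    def n_species(self) -> int:
        return len(self.species)

    def with_params(self, params: ParameterSet) -> "ModelSpec":
        return ModelSpec(params=params, include_tracer=self.include_tracer,
                         compartments=self.compartments)

    def volume(self, species: str) -> float:
        return self.compartments[SPECIES_COMPARTMENT[species]].volume

    # -- reaction-level evaluation (reference path) ------------------------
    def reaction_flux(self, reaction: Reaction, y: np.ndarray) -> float:
        """Extensive flux (mol/day) of one reaction at state ``y``."""
        p = self.params
        vol = self.compartments[reaction.compartment].volume
        get = lambda s: y[self._index[s]]
        if reaction.kind == "constant_flux":
            return getattr(p, reaction.rate_params["v"]) * vol
        if reaction.kind == "synthesis":
            return getattr(p, reaction.rate_params["v"]) * vol
        if reaction.kind == "mass_action":
            return mass_action_flux(getattr(p, reaction.rate_params["k"]),
                                    get(reaction.substrates[0]), vol)
        if reaction.kind == "decay":
            return mass_action_flux(getattr(p, reaction.rate_params["k"]),
                                    get(reaction.substrates[0]), vol)
        if reaction.kind == "mass_action_2":
            a, b = reaction.substrates
            return tf_binding_flux(getattr(p, reaction.rate_params["k"]),
                                   get(a), get(b), vol)
        if reaction.kind == "ferroportin":
            ic = get(reaction.inhibitor) if reaction.inhibitor else 0.0
            hep = get("Hepcidin")
            return ferroportin_rate(get(reaction.substrates[0]), ic, hep,
                                    getattr(p, reaction.rate_params["V"]),
                                    p.Km, p.Ki, vol)
        raise ConfigurationError(f"unknown rate-law kind {reaction.kind!r}")

    def rhs_reference(self, t: float, y: np.ndarray) -> np.ndarray:
        """Reaction-by-reaction ODE right-hand side (validation path)."""
        if not np.all(np.isfinite(y)):
            raise FloatingPointError("non-finite state passed to rhs")
        dydt = np.zeros_like(y)
        for r in self.reactions:
            flux = self.reaction_flux(r, y)
            for s, nu in r.stoich.items():
                dydt[self._index[s]] += nu * flux
        for i, s in enumerate(self.species):
            comp = SPECIES_COMPARTMENT[s]
            if comp != "outside":  # outside pools stay in amount units
                dydt[i] /= self.compartments[comp].volume
        return dydt

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """Compiled ODE right-hand side (production path)."""
        if self.include_tracer:
            return _rhs_tracer(t, y, self._p, self._vols)
        return _rhs_plain(t, y, self._p, self._vols)

    def initial_state(self, total_iron_guess_mg: float = 2.0) -> np.ndarray:
        """A physiologically sensible cold-start state.

        All transferrin apo, hepcidin at its synthesis/degradation balance,
        and the iron distributed crudely across tissues; used only to seed
        the lead-in towards the quasi steady state.
        """
        y = np.zeros(self.n_species)
        ix = self._index
        y[ix["Tf"]] = self.params.TfTotal
        y[ix["Hepcidin"]] = self.params.kHepSyn / self.params.kHepDeg
        mol = total_iron_guess_mg / 1e3 / IRON_MOLAR_MASS
        shares = {"FeRBC": 0.7, "FeRest": 0.2, "FeLiver": 0.08,
                  "FeBM": 0.01, "FeSpleen": 0.005, "FeDuo": 0.005}
        for s, frac in shares.items():
            y[ix[s]] = frac * mol / self.volume(s)
        y[ix["NTBI"]] = 1e-9
        return y


def build_model(params: ParameterSet, include_tracer: bool = True) -> ModelSpec:
    """Assemble the full reaction network for a parameter set."""
    params.validate()
    return ModelSpec(params=params, include_tracer=include_tracer)


# ---------------------------------------------------------------------------
# Derived observables
# ---------------------------------------------------------------------------

def _amounts(model: ModelSpec, y: np.ndarray) -> np.ndarray:
    """Per-species amounts in mol (outside pools already are amounts)."""
    out = np.empty(model.n_species)
    for i, s in enumerate(model.species):
        comp = SPECIES_COMPARTMENT[s]
        vol = 1.0 if comp == "outside" else model.compartments[comp].volume
        out[i] = y[i] * vol
    return out


def total_iron(y: np.ndarray, model: ModelSpec, include_outside: bool = False) -> float:
    """Total body iron in mg, counting di-ferric transferrin twice.

    Excreted (outside) iron is excluded unless ``include_outside`` is set.
    """
    amts = _amounts(model, y)
    mol = 0.0
    for i, s in enumerate(model.species):
        if not include_outside and SPECIES_COMPARTMENT[s] == "outside":
            continue
        mol += IRON_CONTENT[s] * amts[i]
    return mol * IRON_MOLAR_MASS * 1e3


def labeled_iron_mol(y: np.ndarray, model: ModelSpec) -> float:
    """Total radioactive iron (mol) in the system, including excreted."""
    amts = _amounts(model, y)
    return float(sum(LABEL_CONTENT[s] * amts[i]
                     for i, s in enumerate(model.species)))


def tf_saturation(y: np.ndarray, model: ModelSpec) -> float:
    """Transferrin saturation: occupied iron-binding sites in percent."""
    ix = model._index
    occupied = y[ix["Fe1Tf"]]
    if model.include_tracer:
        occupied = occupied + y[ix["Fe1Tf*"]] + 2.0 * (
            y[ix["Fe2Tf"]] + y[ix["Fe2Tf*"]] + y[ix["Fe2Tf**"]])
    else:
        occupied = occupied + 2.0 * y[ix["Fe2Tf"]]
    return 100.0 * occupied / (2.0 * model.params.TfTotal)


def tf_total(y: np.ndarray, model: ModelSpec) -> float:
    """Total transferrin concentration (conserved by the stoichiometry)."""
    ix = model._index
    tot = y[ix["Tf"]] + y[ix["Fe1Tf"]] + y[ix["Fe2Tf"]]
    if model.include_tracer:
        tot = tot + y[ix["Fe1Tf*"]] + y[ix["Fe2Tf*"]] + y[ix["Fe2Tf**"]]
    return float(tot)


# ---------------------------------------------------------------------------
# Compiled right-hand sides
# ---------------------------------------------------------------------------
# State layout (tracer model): see SPECIES.  Parameter layout: see _PACK_ORDER.
# Volume layout: see _VOL_ORDER.

@njit(cache=True)
def _rhs_tracer(t, y, p, vols):  # pragma: no cover - exercised via rhs()
    (kInDuo, kInLiver, kInRBC, kInRest, kInBM,
     kDuoLoss, kRestOut, kBMSpleen,
     VDuo, VLiver, VSpleen, VRest,
     vRBCSpleen, Km, vDiet, kB1, kB2, Ki, kHepSyn, kHepDeg) = p
    Vbm, Vduo, Vliv, Vp, Vrbc, Vrest, Vsp = vols

    FeBM, FeBMt = y[0], y[1]
    FeDuo, FeDuot = y[2], y[3]
    FeLiver, FeLivert = y[4], y[5]
    FeSpleen, FeSpleent = y[6], y[7]
    FeRBC, FeRBCt = y[8], y[9]
    FeRest, FeRestt = y[10], y[11]
    NTBI, NTBIt = y[12], y[13]
    Tf = y[14]
    Fe1Tf, Fe1Tft = y[15], y[16]
    Fe2Tf, Fe2Tft, Fe2Tftt = y[17], y[18], y[19]
    Hep = y[20]

    inh = 1.0 + Hep / Ki

    # ferroportin export (labeled twin competes for the transporter)
    f_duo = VDuo * Vduo * FeDuo / ((Km + FeDuo + FeDuot) * inh)
    f_duot = VDuo * Vduo * FeDuot / ((Km + FeDuo + FeDuot) * inh)
    f_liv = VLiver * Vliv * FeLiver / ((Km + FeLiver + FeLivert) * inh)
    f_livt = VLiver * Vliv * FeLivert / ((Km + FeLiver + FeLivert) * inh)
    f_sp = VSpleen * Vsp * FeSpleen / ((Km + FeSpleen + FeSpleent) * inh)
    f_spt = VSpleen * Vsp * FeSpleent / ((Km + FeSpleen + FeSpleent) * inh)
    f_re = VRest * Vrest * FeRest / ((Km + FeRest + FeRestt) * inh)
    f_ret = VRest * Vrest * FeRestt / ((Km + FeRest + FeRestt) * inh)

    # transferrin loading
    b1 = kB1 * NTBI * Tf * Vp
    b1t = kB1 * NTBIt * Tf * Vp
    b2 = kB2 * NTBI * Fe1Tf * Vp
    b2a = kB2 * NTBI * Fe1Tft * Vp
    b2b = kB2 * NTBIt * Fe1Tf * Vp
    b2t = kB2 * NTBIt * Fe1Tft * Vp

    # transferrin-mediated import: per-form extensive rates
    i1, i1t = Fe1Tf * Vp, Fe1Tft * Vp
    i2, i2a, i2t = Fe2Tf * Vp, Fe2Tft * Vp, Fe2Tftt * Vp

    # erythroid + loss
    m_bmrbc = kInRBC * FeBM * Vbm
    m_bmrbct = kInRBC * FeBMt * Vbm
    m_bmsp = kBMSpleen * FeBM * Vbm
    m_bmspt = kBMSpleen * FeBMt * Vbm
    m_rbcsp = vRBCSpleen * FeRBC * Vrbc
    m_rbcspt = vRBCSpleen * FeRBCt * Vrbc
    m_duol = kDuoLoss * FeDuo * Vduo
    m_duolt = kDuoLoss * FeDuot * Vduo
    m_rol = kRestOut * FeRest * Vrest
    m_rolt = kRestOut * FeRestt * Vrest

    dydt = np.empty(23)
    # bone marrow
    dydt[0] = (kInBM * (i1 + 2.0 * i2 + i2a) - m_bmrbc - m_bmsp) / Vbm
    dydt[1] = (kInBM * (i1t + i2a + 2.0 * i2t) - m_bmrbct - m_bmspt) / Vbm
    # duodenum
    dydt[2] = (vDiet * Vduo + kInDuo * (i1 + 2.0 * i2 + i2a)
               - f_duo - m_duol) / Vduo
    dydt[3] = (kInDuo * (i1t + i2a + 2.0 * i2t) - f_duot - m_duolt) / Vduo
    # liver
    dydt[4] = (kInLiver * (i1 + 2.0 * i2 + i2a) - f_liv) / Vliv
    dydt[5] = (kInLiver * (i1t + i2a + 2.0 * i2t) - f_livt) / Vliv
    # spleen
    dydt[6] = (m_bmsp + m_rbcsp - f_sp) / Vsp
    dydt[7] = (m_bmspt + m_rbcspt - f_spt) / Vsp
    # red blood cells
    dydt[8] = (m_bmrbc - m_rbcsp) / Vrbc
    dydt[9] = (m_bmrbct - m_rbcspt) / Vrbc
    # rest of body
    dydt[10] = (kInRest * (i1 + 2.0 * i2 + i2a) - f_re - m_rol) / Vrest
    dydt[11] = (kInRest * (i1t + i2a + 2.0 * i2t) - f_ret - m_rolt) / Vrest
    # plasma NTBI
    dydt[12] = (f_duo + f_liv + f_sp + f_re - b1 - b2 - b2a) / Vp
    dydt[13] = (f_duot + f_livt + f_spt + f_ret - b1t - b2b - b2t) / Vp
    # transferrin forms; kSum is the total import rate constant
    kSum = kInDuo + kInLiver + kInRest + kInBM
    dydt[14] = (kSum * (i1 + i1t + i2 + i2a + i2t) - b1 - b1t) / Vp
    dydt[15] = (b1 - b2 - b2b - kSum * i1) / Vp
    dydt[16] = (b1t - b2a - b2t - kSum * i1t) / Vp
    dydt[17] = (b2 - kSum * i2) / Vp
    dydt[18] = (b2a + b2b - kSum * i2a) / Vp
    dydt[19] = (b2t - kSum * i2t) / Vp
    # hepcidin
    dydt[20] = kHepSyn - kHepDeg * Hep
    # outside (amount units)
    dydt[21] = m_duol + m_rol
    dydt[22] = m_duolt + m_rolt
    return dydt


#: tracer-model index of each tracer-free species, in PLAIN_SPECIES order
_PLAIN_TO_TRACER = np.array([0, 2, 4, 6, 8, 10, 12, 14, 15, 17, 20, 21])


@njit(cache=True)
def _rhs_plain(t, y, p, vols):  # pragma: no cover - exercised via rhs()
    y23 = np.zeros(23)
    for i in range(12):
        y23[_PLAIN_TO_TRACER[i]] = y[i]
    d23 = _rhs_tracer(t, y23, p, vols)
    dydt = np.empty(12)
    for i in range(12):
        dydt[i] = d23[_PLAIN_TO_TRACER[i]]
    return dydt
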