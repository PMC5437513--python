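"""Readers, writers, configuration and SBML exchange.

On-disk conventions: concentrations in molar, time in days, volumes in
liters.  Tracer datasets travel as CSV with columns
``time_days,pool,fraction_of_dose[,sd]``; parameter sets as flat JSON with
the canonical rate-constant names; run configuration as YAML with unknown
keys rejected.  Models can be exported as SBML Level 3 Version 1 for
exchange with simulators such as COPASI; the exporter is paired with a
structural validator and a MathML evaluator used to cross-check the
exported kinetic laws numerically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd
import yaml

from .model import (
    ConfigurationError,
    ModelSpec,
    ParameterSet,
    Reaction,
    SPECIES_COMPARTMENT,
)
from .protocols import REPORTED_POOLS
from .synthetic import TracerDataset, validate_dataset_frame

logger = logging.getLogger("ferrokin")

#: accepted spellings of pool names in input files
_POOL_ALIASES = {
    "plasma": "plasma", "serum": "plasma",
    "duodenum": "duodenum", "duo": "duodenum",
    "bone_marrow": "bone_marrow", "bone marrow": "bone_marrow",
    "bm": "bone_marrow", "marrow": "bone_marrow",
    "rbc": "rbc", "red blood cells": "rbc", "red_blood_cells": "rbc",
    "erythrocytes": "rbc",
    "liver": "liver",
    "spleen": "spleen",
    "rest": "rest", "rest_of_body": "rest", "rest of body": "rest",
    "excreted": "excreted", "outside": "excreted", "feces": "excreted",
}


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

def read_dataset(path, meta: Optional[Dict] = None) -> TracerDataset:
    """Read and validate a tracer dataset CSV.

    Pool names are normalized to the canonical vocabulary; a missing
    ``sd`` column simply yields a dataset without uncertainties (fitted
    unweighted).  Schema violations raise with the offending row number.
    """
    df = pd.read_csv(path)
    required = {"time_days", "pool", "fraction_of_dose"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    norm = []
    for row, pool in df["pool"].items():
        key = str(pool).strip().lower()
        if key not in _POOL_ALIASES:
            raise ValueError(f"{path}: row {row}: unknown pool name {pool!r}")
        norm.append(_POOL_ALIASES[key])
    df = df.assign(pool=norm)
    if "sd" in df.columns and df["sd"].isna().all():
        df = df.drop(columns=["sd"])
    validate_dataset_frame(df)
    return TracerDataset(df=df, meta=dict(meta or {}, source=str(path)))


def write_dataset(dataset: TracerDataset, path) -> None:
    dataset.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

def read_params(path) -> ParameterSet:
    """Read a flat-JSON parameter set (canonical key names, M/day units)."""
    with open(path) as fh:
        return ParameterSet.from_dict(json.load(fh))


def write_params(params: ParameterSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=2, sort_keys=True)


def read_params_from_sbml(path) -> ParameterSet:
    """Extract a parameter set from an SBML file's global parameters.

    Intended for loading deposited model files (e.g. the BioModels entries
    for this system, see ``synthetic.BIOMODELS_ACCESSIONS``) so the exact
    hepcidin constants used there can replace the package defaults.
    Unknown global parameters are ignored; missing required ones raise.
    """
    with open(path) as fh:
        doc = parse_sbml(fh.read())
    known = set(ParameterSet.names())
    found = {k: v for k, v in doc["parameters"].items() if k in known}
    return ParameterSet.from_dict(found)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "seed": int,
    "outdir": str,
    "params_fixture_column": int,
    "params_file": str,
    "params": dict,
    "protocol": dict,
    "fit": dict,
    "datasets": list,
}

_PROTOCOL_KEYS = {"leadin_days", "diet_leadin_days", "injection_dose_mol",
                  "observation_days", "diet_vDiet", "diet_kHepSyn",
                  "horizon_days"}
_FIT_KEYS = {"free", "per_diet_free", "decades", "lam", "mu", "generations",
             "pf", "constraint_mg", "weighted", "seeds"}


@dataclass
class RunConfig:
    """Validated run configuration (single seed governs all randomness)."""

    seed: int = 0
    outdir: str = "."
    params_fixture_column: Optional[int] = None
    params_file: Optional[str] = None
    params: Optional[Dict[str, float]] = None
    protocol: Dict = field(default_factory=dict)
    fit: Dict = field(default_factory=dict)
    datasets: List[Dict] = field(default_factory=list)

    def parameter_set(self) -> ParameterSet:
        from .synthetic import fixture_table2
        sources = [self.params_fixture_column is not None,
                   self.params_file is not None, self.params is not None]
        if sum(sources) > 1:
            raise ConfigurationError("give exactly one parameter source")
        if self.params is not None:
            return ParameterSet.from_dict(self.params)
        if self.params_file is not None:
            return read_params(self.params_file)
        return fixture_table2(self.params_fixture_column or 6)


def load_config(path) -> RunConfig:
    """Load and schema-check a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    unknown = set(raw) - set(_CONFIG_KEYS)
    if unknown:
        raise ConfigurationError(f"{path}: unknown config key(s) {sorted(unknown)}")
    for section, allowed in (("protocol", _PROTOCOL_KEYS), ("fit", _FIT_KEYS)):
        extra = set(raw.get(section) or {}) - allowed
        if extra:
            raise ConfigurationError(
                f"{path}: unknown {section} key(s) {sorted(extra)}")
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# SBML Level 3 Version 1 export
# ---------------------------------------------------------------------------

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _sid(name: str) -> str:
    """Sanitize a species/reaction name into an SBML identifier."""
    return name.replace("**", "_2tr").replace("*", "_tr").replace("@", "_")


def _mathml(expr) -> ET.Element:
    """Build MathML from a nested prefix tuple, e.g. ('times', 'k', 'S')."""
    if isinstance(expr, (int, float)):
        cn = ET.Element(f"{{{MATHML_NS}}}cn")
        cn.text = repr(float(expr))
        return cn
    if isinstance(expr, str):
        ci = ET.Element(f"{{{MATHML_NS}}}ci")
        ci.text = f" {expr} "
        return ci
    op, *args = expr
    apply_el = ET.Element(f"{{{MATHML_NS}}}apply")
    apply_el.append(ET.Element(f"{{{MATHML_NS}}}{op}"))
    for a in args:
        apply_el.append(_mathml(a))
    return apply_el


def _rate_expression(r: Reaction, model: ModelSpec):
    comp = r.compartment
    p = r.rate_params
    if r.kind in ("constant_flux", "synthesis"):
        return ("times", p["v"], comp)
    if r.kind in ("mass_action", "decay"):
        return ("times", p["k"], _sid(r.substrates[0]), comp)
    if r.kind == "mass_action_2":
        a, b = r.substrates
        return ("times", p["k"], _sid(a), _sid(b), comp)
    if r.kind == "ferroportin":
        s = _sid(r.substrates[0])
        ic = _sid(r.inhibitor) if r.inhibitor else 0.0
        return ("divide",
                ("times", p["V"], comp, s),
                ("times",
                 ("plus", p["Km"], s, ic),
                 ("plus", 1.0, ("divide", "Hepcidin", p["Ki"]))))
    raise ConfigurationError(f"no SBML rate law for kind {r.kind!r}")


def export_sbml(model: ModelSpec, model_id: str = "mouse_iron_distribution") -> str:
    """Serialize a model as SBML L3V1 (compartments, species, kinetic laws).

    Radioactive species names are sanitized (``FeBM*`` -> ``FeBM_tr``,
    ``Fe2Tf**`` -> ``Fe2Tf_2tr``).  The export is structurally validated
    before being returned.
    """
    ET.register_namespace("", SBML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml",
                      {"level": "3", "version": "1"})
    mdl = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {"id": model_id})

    comps_el = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    for name, comp in model.compartments.items():
        ET.SubElement(comps_el, f"{{{SBML_NS}}}compartment", {
            "id": name, "constant": "true",
            "size": repr(comp.volume if comp.volume > 0 else 1.0),
            "spatialDimensions": "3"})

    sp_el = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for i, s in enumerate(model.species):
        comp = SPECIES_COMPARTMENT[s]
        amount_based = comp == "outside"
        attrs = {"id": _sid(s), "name": s, "compartment": comp,
                 "constant": "false", "boundaryCondition": "false",
                 "hasOnlySubstanceUnits": "true" if amount_based else "false"}
        if amount_based:
            attrs["initialAmount"] = "0.0"
        else:
            attrs["initialConcentration"] = "0.0"
        ET.SubElement(sp_el, f"{{{SBML_NS}}}species", attrs)

    par_el = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfParameters")
    for name, value in model.params.to_dict().items():
        ET.SubElement(par_el, f"{{{SBML_NS}}}parameter", {
            "id": name, "value": repr(value), "constant": "true"})

    rx_el = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for r in model.reactions:
        rel = ET.SubElement(rx_el, f"{{{SBML_NS}}}reaction", {
            "id": _sid(r.name), "reversible": "false"})
        reactants = {s: -nu for s, nu in r.stoich.items() if nu < 0}
        products = {s: nu for s, nu in r.stoich.items() if nu > 0}
        if reactants:
            lr = ET.SubElement(rel, f"{{{SBML_NS}}}listOfReactants")
            for s, nu in reactants.items():
                ET.SubElement(lr, f"{{{SBML_NS}}}speciesReference", {
                    "species": _sid(s), "stoichiometry": repr(float(nu)),
                    "constant": "true"})
        if products:
            lp = ET.SubElement(rel, f"{{{SBML_NS}}}listOfProducts")
            for s, nu in products.items():
                ET.SubElement(lp, f"{{{SBML_NS}}}speciesReference", {
                    "species": _sid(s), "stoichiometry": repr(float(nu)),
                    "constant": "true"})
        modifiers = set(r.substrates) | ({r.inhibitor} if r.inhibitor else set())
        if r.kind == "ferroportin":
            modifiers.add("Hepcidin")
        modifiers -= set(r.stoich)
        if modifiers:
            lm = ET.SubElement(rel, f"{{{SBML_NS}}}listOfModifiers")
            for s in sorted(modifiers):
                ET.SubElement(lm, f"{{{SBML_NS}}}modifierSpeciesReference",
                              {"species": _sid(s)})
        kl = ET.SubElement(rel, f"{{{SBML_NS}}}kineticLaw")
        math = ET.Element(f"{{{MATHML_NS}}}math")
        math.append(_mathml(_rate_expression(r, model)))
        kl.append(math)

    xml = ET.tostring(sbml, encoding="unicode", xml_declaration=True)
    issues = validate_sbml(xml)
    if issues:
        raise ConfigurationError("SBML export failed validation: "
                                 + "; ".join(issues))
    return xml


# ---------------------------------------------------------------------------
# SBML structural validation and numeric cross-checks
# ---------------------------------------------------------------------------

def _q(tag: str, ns: str = SBML_NS) -> str:
    return f"{{{ns}}}{tag}"


def parse_sbml(xml: str) -> Dict:
    """Parse an SBML string into ids: species, compartments, parameters,
    reactions (with their MathML kinetic-law elements)."""
    root = ET.fromstring(xml)
    mdl = root.find(_q("model"))
    if mdl is None:
        raise ValueError("no <model> element")
    out = {
        "compartments": {c.get("id"): float(c.get("size", "1"))
                         for c in mdl.iter(_q("compartment"))},
        "species": {s.get("id"): s.get("compartment")
                    for s in mdl.iter(_q("species"))},
        "parameters": {p.get("id"): float(p.get("value", "nan"))
                       for p in mdl.iter(_q("parameter"))},
        "reactions": {},
    }
    for r in mdl.iter(_q("reaction")):
        math = r.find(f"{_q('kineticLaw')}/{_q('math', MATHML_NS)}")
        out["reactions"][r.get("id")] = math
    return out


def validate_sbml(xml: str) -> List[str]:
    """Structural validation; returns a list of issues (empty = valid)."""
    issues: List[str] = []
    try:
        doc = parse_sbml(xml)
    except (ET.ParseError, ValueError) as exc:
        return [f"parse failure: {exc}"]
    for group in ("compartments", "species", "parameters", "reactions"):
        ids = list(doc[group])
        if len(ids) != len(set(ids)):
            issues.append(f"duplicate ids in {group}")
        if any(i is None for i in ids):
            issues.append(f"missing id in {group}")
    for sid, comp in doc["species"].items():
        if comp not in doc["compartments"]:
            issues.append(f"species {sid}: unknown compartment {comp}")
    known = (set(doc["species"]) | set(doc["parameters"])
             | set(doc["compartments"]))
    for rid, math in doc["reactions"].items():
        if math is None:
            issues.append(f"reaction {rid}: missing kinetic law")
            continue
        for ci in math.iter(_q("ci", MATHML_NS)):
            ref = (ci.text or "").strip()
            if ref not in known:
                issues.append(f"reaction {rid}: unresolved symbol {ref!r}")
    return issues


def evaluate_mathml(node: ET.Element, env: Dict[str, float]) -> float:
    """Evaluate the MathML subset emitted by :func:`export_sbml`."""
    tag = node.tag.split("}")[-1]
    if tag == "math":
        children = list(node)
        if len(children) != 1:
            raise ValueError("math element must have one child")
        return evaluate_mathml(children[0], env)
    if tag == "cn":
        return float(node.text)
    if tag == "ci":
        return env[(node.text or "").strip()]
    if tag == "apply":
        op, *args = list(node)
        opname = op.tag.split("}")[-1]
        vals = [evaluate_mathml(a, env) for a in args]
        if opname == "times":
            return float(np.prod(vals))
        if opname == "plus":
            return float(np.sum(vals))
        if opname == "divide":
            return vals[0] / vals[1]
        if opname == "minus":
            return vals[0] - vals[1] if len(vals) == 2 else -vals[0]
        raise ValueError(f"unsupported operator {opname!r}")
    raise ValueError(f"unsupported MathML element {tag!r}")


def evaluate_kinetic_law(xml: str, reaction_id: str,
                         env: Dict[str, float]) -> float:
    """Numerically evaluate one exported kinetic law in an environment
    mapping species/parameter/compartment ids to values."""
    doc = parse_sbml(xml)
    math = doc["reactions"][reaction_id]
    if math is None:
        raise ValueError(f"reaction {reaction_id!r} has no kinetic law")
    full_env = dict(doc["parameters"])
    full_env.update(doc["compartments"])
    full_env.update(env)
    return evaluate_mathml(math, full_env)
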