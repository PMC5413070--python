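"""Core constraint-based model structures, I/O, normalization and validation.

A :class:`MetabolicModel` is a plain stoichiometric network: metabolites,
reactions with bounds, one designated biomass reaction, and a metabolite
namespace tag (``bigg``, ``modelseed`` or ``metanetx``).  Sign convention
throughout: negative stoichiometric coefficients are substrates, positive are
products; for exchange reactions positive flux is secretion and negative flux
is uptake.

Models are read/written as SBML Level 3 (with the fbc flux-bounds extension)
via libsbml, and as a flat JSON dialect used by the fixtures module.
"""
from __future__ import annotations

import copy as _copy
import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

from ._lp import LPResult, SolverError, solve_lp

log = logging.getLogger(__name__)

NAMESPACES = ("bigg", "modelseed", "metanetx")

#: default magnitude used to open exchange bounds in the "maximally rich"
#: environment; +-1000 is the de-facto unbounded convention in published GSMs.
RICH_BOUND = 1000.0

_SBO_EXCHANGE = 627

# Per-namespace id/name patterns identifying the non-growth-associated ATP
# maintenance reaction (its lower bound is zeroed during normalization).
ATPM_ID_PATTERNS = {
    "bigg": ("atpm",),
    "modelseed": ("rxn00062",),
    "metanetx": ("atpm", "mnxr96136"),
}
ATPM_NAME_SUBSTRINGS = ("maintenance", "atpm")


class ModelError(ValueError):
    """The document parsed but does not describe a consistent model."""


class FormatError(ValueError):
    """The document could not be parsed at all."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None
    boundary: bool = False   # SBML boundaryCondition: excluded from S.v = 0

    def copy(self) -> "Metabolite":
        return _copy.copy(self)


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -RICH_BOUND
    upper_bound: float = RICH_BOUND
    name: str = ""
    gene_rule: str | None = None
    is_exchange: bool = False
    is_dissipation: bool = False

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        r = _copy.copy(self)
        r.stoichiometry = dict(self.stoichiometry)
        return r


@dataclass
class BalanceFinding:
    reaction_id: str
    element_deltas: dict[str, float] = field(default_factory=dict)
    charge_delta: float | None = None
    balanced: bool | None = None
    skipped: str | None = None   # reason the reaction was not checked


@dataclass
class MetabolicModel:
    id: str
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    biomass_reaction_id: str
    namespace: str = "bigg"
    notes: dict = field(default_factory=dict)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites={k: v.copy() for k, v in self.metabolites.items()},
            reactions={k: v.copy() for k, v in self.reactions.items()},
            biomass_reaction_id=self.biomass_reaction_id,
            namespace=self.namespace,
            notes=_copy.deepcopy(self.notes),
        )

    # -- structure -----------------------------------------------------------

    def validate(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ModelError(f"unknown namespace {self.namespace!r}; "
                             f"expected one of {NAMESPACES}")
        if self.biomass_reaction_id not in self.reactions:
            raise ModelError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model")
        dangling = sorted({
            met for r in self.reactions.values() for met in r.stoichiometry
            if met not in self.metabolites})
        if dangling:
            raise ModelError(
                "reactions reference undeclared metabolites: "
                + ", ".join(dangling))
        for m in self.metabolites.values():
            if not m.compartment:
                raise ModelError(f"metabolite {m.id!r} has empty compartment")
        for r in self.reactions.values():
            if not r.stoichiometry:
                raise ModelError(f"reaction {r.id!r} has empty stoichiometry")
            if r.lower_bound > r.upper_bound:
                raise ModelError(
                    f"reaction {r.id!r} has lower_bound > upper_bound")

    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.reactions.values() if r.is_exchange]

    def stoichiometric_matrix(self):
        """Sparse S (metabolites x reactions), boundary species excluded.

        Returns (S, met_index, rxn_ids) where met_index maps metabolite id to
        row and rxn_ids gives the column order.
        """
        met_index = {mid: i for i, mid in enumerate(
            m.id for m in self.metabolites.values() if not m.boundary)}
        rxn_ids = self.reaction_ids()
        rows, cols, vals = [], [], []
        for j, rid in enumerate(rxn_ids):
            for mid, coef in self.reactions[rid].stoichiometry.items():
                i = met_index.get(mid)
                if i is not None:
                    rows.append(i)
                    cols.append(j)
                    vals.append(float(coef))
        S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(met_index), len(rxn_ids)))
        return S, met_index, rxn_ids


# ---------------------------------------------------------------------------
# exchange / biomass identification

def _infer_exchanges(model: MetabolicModel) -> None:
    """Flag exchange reactions in place (explicit flags are left untouched).

    A reaction touching exactly one non-boundary metabolite is an exchange;
    the biomass pseudo-reaction is never an exchange.  EX_/DM_/SK_ id prefixes
    are honored as an additional hint.
    """
    for r in model.reactions.values():
        if r.is_exchange or r.id == model.biomass_reaction_id:
            continue
        if r.id.startswith(("EX_", "DM_", "SK_", "R_EX_")):
            r.is_exchange = True
            continue
        nonboundary = [m for m in r.stoichiometry
                       if not model.metabolites.get(m, Metabolite(m)).boundary]
        if len(nonboundary) == 1 and not r.is_dissipation:
            r.is_exchange = True


_BIOMASS_HINTS = ("biomass", "growth", "bio1", "bio00001")


def _guess_biomass(reactions: dict[str, Reaction]) -> str | None:
    for rid, r in reactions.items():
        hay = (rid + " " + r.name).lower()
        if any(h in hay for h in _BIOMASS_HINTS):
            return rid
    return None


# ---------------------------------------------------------------------------
# JSON dialect

def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "namespace": model.namespace,
        "biomass_reaction_id": model.biomass_reaction_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment,
             "formula": m.formula, "charge": m.charge, "boundary": m.boundary}
            for m in model.metabolites.values()],
        "reactions": [
            {"id": r.id, "name": r.name,
             "stoichiometry": dict(r.stoichiometry),
             "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
             "gene_rule": r.gene_rule, "is_exchange": r.is_exchange,
             "is_dissipation": r.is_dissipation}
            for r in model.reactions.values()],
    }


def model_from_dict(doc: dict, namespace: str | None = None) -> MetabolicModel:
    try:
        mets = {m["id"]: Metabolite(
            id=m["id"], name=m.get("name", ""),
            compartment=m.get("compartment", "c"),
            formula=m.get("formula"), charge=m.get("charge"),
            boundary=bool(m.get("boundary", False)))
            for m in doc["metabolites"]}
        rxns = {r["id"]: Reaction(
            id=r["id"], stoichiometry={k: float(v) for k, v in
                                       r["stoichiometry"].items()},
            lower_bound=float(r.get("lower_bound", -RICH_BOUND)),
            upper_bound=float(r.get("upper_bound", RICH_BOUND)),
            name=r.get("name", ""), gene_rule=r.get("gene_rule"),
            is_exchange=bool(r.get("is_exchange", False)),
            is_dissipation=bool(r.get("is_dissipation", False)))
            for r in doc["reactions"]}
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed JSON model document: {exc}") from exc
    bio = doc.get("biomass_reaction_id") or _guess_biomass(rxns)
    if bio is None:
        raise ModelError(
            "no biomass reaction: none declared and no id/name matched "
            f"heuristics {_BIOMASS_HINTS}")
    model = MetabolicModel(
        id=doc.get("id", "model"), metabolites=mets, reactions=rxns,
        biomass_reaction_id=bio,
        namespace=namespace or doc.get("namespace", "bigg"))
    _infer_exchanges(model)
    model.validate()
    return model


def save_json(model: MetabolicModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def load_json(source, namespace: str | None = None) -> MetabolicModel:
    if isinstance(source, dict):
        return model_from_dict(source, namespace)
    text = Path(source).read_text() if not str(source).lstrip().startswith("{") \
        else str(source)
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON: {exc}") from exc
    return model_from_dict(doc, namespace)


# ---------------------------------------------------------------------------
# SBML (Level 3 + fbc)

def _sid(prefix: str, raw: str) -> str:
    s = re.sub(r"[^A-Za-z0-9_]", "__", raw)
    return prefix + s


def _unsid(prefix: str, sid: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def save_sbml(model: MetabolicModel, path=None) -> str:
    """Serialize to SBML L3V1 with fbc v2 flux bounds; returns the XML text."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sid("", model.id) or "model")
    sm.setNotes(f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>namespace: {model.namespace}</p></body>")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(False)

    for cid in sorted({m.compartment for m in model.metabolites.values()}):
        c = sm.createCompartment()
        c.setId(_sid("", cid))
        c.setConstant(True)
        c.setSize(1.0)

    for met in model.metabolites.values():
        s = sm.createSpecies()
        s.setId(_sid("M_", met.id))
        s.setName(met.name or met.id)
        s.setCompartment(_sid("", met.compartment))
        s.setConstant(False)
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(met.boundary)
        sp = s.getPlugin("fbc")
        if met.formula:
            sp.setChemicalFormula(met.formula)
        if met.charge is not None:
            sp.setCharge(int(met.charge))

    bound_params: dict[float, str] = {}

    def _param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        r = sm.createReaction()
        r.setId(_sid("R_", rxn.id))
        r.setName(rxn.name or rxn.id)
        r.setReversible(rxn.lower_bound < 0)
        r.setFast(False)
        if rxn.is_exchange:
            r.setSBOTerm(_SBO_EXCHANGE)
        rp = r.getPlugin("fbc")
        rp.setLowerFluxBound(_param(rxn.lower_bound))
        rp.setUpperFluxBound(_param(rxn.upper_bound))
        for mid, coef in rxn.stoichiometry.items():
            sr = r.createReactant() if coef < 0 else r.createProduct()
            sr.setSpecies(_sid("M_", mid))
            sr.setStoichiometry(abs(float(coef)))
            sr.setConstant(True)

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction(_sid("R_", model.biomass_reaction_id))
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    xml = libsbml.writeSBMLToString(doc)
    if path is not None:
        Path(path).write_text(xml)
    return xml


def load_sbml(source, namespace: str | None = None) -> MetabolicModel:
    """Parse SBML text or a file path into a MetabolicModel.

    fbc flux bounds are read when present (default +-1000 otherwise); the
    biomass reaction comes from the active fbc objective, falling back to
    id/name heuristics.  Exchanges are taken from SBO terms or inferred from
    single-metabolite topology; reactions with ids starting ``EDR_`` are
    treated as dissipation reactions.
    """
    import libsbml

    text = str(source)
    if "<" not in text:   # a path, not an XML document
        text = Path(source).read_text()
    doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [doc.getError(i).getMessage()
                for i in range(doc.getNumErrors())]
        raise FormatError("SBML parse failure: " + "; ".join(msgs[:3]))
    sm = doc.getModel()
    if sm is None:
        raise FormatError("SBML document contains no model")

    if namespace is None:
        notes = sm.getNotesString() if sm.isSetNotes() else ""
        match = re.search(r"namespace:\s*(\w+)", notes)
        namespace = match.group(1) if match else "bigg"

    mets: dict[str, Metabolite] = {}
    for i in range(sm.getNumSpecies()):
        s = sm.getSpecies(i)
        sp = s.getPlugin("fbc")
        mid = _unsid("M_", s.getId())
        mets[mid] = Metabolite(
            id=mid, name=s.getName() or "",
            compartment=s.getCompartment() or "c",
            formula=(sp.getChemicalFormula()
                     if sp is not None and sp.isSetChemicalFormula() else None),
            charge=(sp.getCharge()
                    if sp is not None and sp.isSetCharge() else None),
            boundary=bool(s.getBoundaryCondition()))

    params = {sm.getParameter(i).getId(): sm.getParameter(i).getValue()
              for i in range(sm.getNumParameters())}

    rxns: dict[str, Reaction] = {}
    dangling: set[str] = set()
    for i in range(sm.getNumReactions()):
        r = sm.getReaction(i)
        rid = _unsid("R_", r.getId())
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            sr = r.getReactant(j)
            mid = _unsid("M_", sr.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) - sr.getStoichiometry()
        for j in range(r.getNumProducts()):
            sr = r.getProduct(j)
            mid = _unsid("M_", sr.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) + sr.getStoichiometry()
        dangling.update(m for m in stoich if m not in mets)
        rp = r.getPlugin("fbc")
        lb, ub = -RICH_BOUND, RICH_BOUND
        if rp is not None and rp.isSetLowerFluxBound():
            lb = params.get(rp.getLowerFluxBound(), lb)
        elif not r.getReversible():
            lb = 0.0
        if rp is not None and rp.isSetUpperFluxBound():
            ub = params.get(rp.getUpperFluxBound(), ub)
        rxns[rid] = Reaction(
            id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
            name=r.getName() or "",
            is_exchange=(r.getSBOTerm() == _SBO_EXCHANGE),
            is_dissipation=rid.startswith("EDR_"))
    if dangling:
        raise ModelError("reactions reference undeclared metabolites: "
                         + ", ".join(sorted(dangling)))

    bio = None
    mplug = sm.getPlugin("fbc")
    if mplug is not None and mplug.getActiveObjective() is not None:
        ao = mplug.getActiveObjective()
        if ao.getNumFluxObjectives() > 0:
            bio = _unsid("R_", ao.getFluxObjective(0).getReaction())
    if bio is None or bio not in rxns:
        bio = _guess_biomass(rxns)
    if bio is None:
        raise ModelError(
            "no biomass reaction: no fbc objective and no id/name matched "
            f"heuristics {_BIOMASS_HINTS}")

    model = MetabolicModel(id=sm.getId() or "model", metabolites=mets,
                           reactions=rxns, biomass_reaction_id=bio,
                           namespace=namespace)
    _infer_exchanges(model)
    model.validate()
    return model


def load_model(source, namespace: str | None = None) -> MetabolicModel:
    """Load an SBML or JSON model document (path or raw text/dict)."""
    if isinstance(source, dict):
        return model_from_dict(source, namespace)
    text = str(source)
    if text.lstrip().startswith("<"):
        return load_sbml(text, namespace)
    if text.lstrip().startswith("{"):
        return load_json(text, namespace)
    path = Path(source)
    if not path.exists():
        raise FormatError(f"no such model file: {source}")
    if path.suffix.lower() == ".json":
        return load_json(path, namespace)
    return load_sbml(path, namespace)


# ---------------------------------------------------------------------------
# normalization

def normalize_model(model: MetabolicModel):
    """Return (normalized copy, change log).

    Exchange reactions are rewritten to the secretion-positive convention and
    the ATP maintenance reaction's positive lower bound (a forced non-growth
    ATP drain) is reset to zero.  The change log records every altered bound;
    the operation is idempotent.
    """
    mm = model.copy()
    changelog: list[dict] = []
    for r in mm.reactions.values():
        if not r.is_exchange:
            continue
        single = [m for m in r.stoichiometry
                  if not mm.metabolites[m].boundary]
        mid = single[0] if single else next(iter(r.stoichiometry))
        if r.stoichiometry[mid] > 0:   # written as uptake-positive: flip
            old = (r.lower_bound, r.upper_bound)
            r.stoichiometry = {k: -v for k, v in r.stoichiometry.items()}
            r.lower_bound, r.upper_bound = -old[1], -old[0]
            changelog.append({
                "reaction": r.id, "change": "exchange_direction_flipped",
                "old_bounds": old,
                "new_bounds": (r.lower_bound, r.upper_bound)})
    atpm = find_atpm(mm)
    if atpm is None:
        log.info("model %s: no ATP maintenance reaction matched", mm.id)
    elif mm.reactions[atpm].lower_bound > 0:
        old = mm.reactions[atpm].lower_bound
        mm.reactions[atpm].lower_bound = 0.0
        changelog.append({"reaction": atpm, "change": "atpm_lower_bound_zeroed",
                          "old_bounds": (old, mm.reactions[atpm].upper_bound),
                          "new_bounds": (0.0, mm.reactions[atpm].upper_bound)})
    mm.notes.setdefault("normalization_log", []).extend(changelog)
    return mm, changelog


def find_atpm(model: MetabolicModel,
              extra_patterns: tuple[str, ...] = ()) -> str | None:
    """Locate the ATP maintenance reaction by per-namespace id/name patterns."""
    idpats = ATPM_ID_PATTERNS.get(model.namespace, ()) + extra_patterns
    for r in model.reactions.values():
        if r.is_exchange or r.is_dissipation:
            continue
        rid = r.id.lower()
        if any(rid == p or rid.startswith(p) for p in idpats):
            return r.id
    for r in model.reactions.values():
        if r.is_exchange or r.is_dissipation:
            continue
        if any(s in r.name.lower() for s in ATPM_NAME_SUBSTRINGS):
            return r.id
    return None


# ---------------------------------------------------------------------------
# FBA helpers

def biomass_optimum(model: MetabolicModel, rich: bool = True,
                    rich_bound: float = RICH_BOUND) -> float:
    """Maximal biomass flux; with ``rich=True`` every exchange is opened to
    [-rich_bound, rich_bound] (the maximally rich environment)."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    bounds = []
    for rid in rxn_ids:
        r = model.reactions[rid]
        if rich and r.is_exchange:
            bounds.append((-rich_bound, rich_bound))
        else:
            bounds.append((r.lower_bound, r.upper_bound))
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(model.biomass_reaction_id)] = 1.0
    res = solve_lp(c, bounds, A_eq=S, b_eq=np.zeros(S.shape[0]), maximize=True)
    if not res.optimal:
        raise SolverError(f"growth LP not optimal: status {res.status}")
    return max(res.objective, 0.0)


def check_viability(model: MetabolicModel, threshold: float = 1e-6,
                    rich_bound: float = RICH_BOUND):
    """(is_viable, optimum): can the model grow on the rich medium?"""
    opt = biomass_optimum(model, rich=True, rich_bound=rich_bound)
    return opt >= threshold, opt


# ---------------------------------------------------------------------------
# mass / charge balance

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation elemental formula into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"unparseable formula {formula!r}")
        pos = match.end()
        counts[match.group(1)] = counts.get(match.group(1), 0) + int(
            match.group(2) or 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"unparseable formula {formula!r}")
    return counts


def check_balance(model: MetabolicModel,
                  tolerance: float = 1e-6) -> list[BalanceFinding]:
    """Per-reaction elemental and charge deltas from metabolite formulas.

    Exchange and dissipation reactions are exempt (the latter are electron
    unbalanced by design); reactions whose metabolites lack formulas are
    flagged as skipped, never silently passed.
    """
    findings = []
    for r in model.reactions.values():
        if r.is_exchange or r.is_dissipation:
            continue
        deltas: dict[str, float] = {}
        charge: float | None = 0.0
        skipped = None
        for mid, coef in r.stoichiometry.items():
            met = model.metabolites[mid]
            if met.formula is None:
                skipped = "no formula"
                break
            try:
                counts = parse_formula(met.formula)
            except ValueError:
                log.warning("reaction %s: unparseable formula %r on %s",
                            r.id, met.formula, mid)
                skipped = f"unparseable formula on {mid}"
                break
            for el, n in counts.items():
                deltas[el] = deltas.get(el, 0.0) + coef * n
            if charge is not None and met.charge is not None:
                charge += coef * met.charge
            else:
                charge = None
        if skipped:
            findings.append(BalanceFinding(r.id, skipped=skipped))
            continue
        deltas = {el: d for el, d in deltas.items() if abs(d) > tolerance}
        balanced = not deltas and (charge is None or abs(charge) <= tolerance)
        findings.append(BalanceFinding(
            r.id, element_deltas=deltas, charge_delta=charge,
            balanced=balanced))
    return findings
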