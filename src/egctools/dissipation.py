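"""Energy-dissipation reactions (EDRs) and their integration into a model.

An EDR irreversibly discharges one energy metabolite -- e.g. for ATP the
reaction ``atp + h2o -> adp + pi + h`` -- so that any cycle able to charge
that metabolite from nothing becomes a detectable internal (type-III) cycle.
Fifteen EDRs are used: the five NTPs, five redox carriers (NADH, NADPH,
FADH2, FMNH2 plus the three quinols), acetyl-CoA, L-glutamate, and the
transmembrane proton gradient.  Redox EDRs are deliberately electron
unbalanced: for NADH the template is ``nadh -> nad + h`` with no electron
acceptor, because a balanced acceptor could be recycled internally and the
reaction would then carry flux even without an energy-generating cycle.

The stoichiometry templates shipped here are reconstructions following the
published ATP and NADH forms; users can replace them via a TSV catalog.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from .model_core import MetabolicModel, Reaction

log = logging.getLogger(__name__)

#: canonical labels of the 15 energy metabolites (proton gradient included).
LABELS = ("ATP", "CTP", "GTP", "UTP", "ITP", "NADH", "NADPH", "FADH2",
          "FMNH2", "Q8H2", "MQL8", "2DMMQL8", "ACCOA", "GLU", "HGRADIENT")

#: default EDR upper bound -- EDRs are exempt from the +-1 internal clamp.
EDR_UPPER = 1000.0

# Templates use generic base ids plus a compartment role in brackets.
_TEMPLATES = {
    "ATP": "atp[c] + h2o[c] -> adp[c] + pi[c] + h[c]",
    "CTP": "ctp[c] + h2o[c] -> cdp[c] + pi[c] + h[c]",
    "GTP": "gtp[c] + h2o[c] -> gdp[c] + pi[c] + h[c]",
    "UTP": "utp[c] + h2o[c] -> udp[c] + pi[c] + h[c]",
    "ITP": "itp[c] + h2o[c] -> idp[c] + pi[c] + h[c]",
    "NADH": "nadh[c] -> nad[c] + h[c]",
    "NADPH": "nadph[c] -> nadp[c] + h[c]",
    "FADH2": "fadh2[c] -> fad[c] + 2 h[c]",
    "FMNH2": "fmnh2[c] -> fmn[c] + 2 h[c]",
    "Q8H2": "q8h2[c] -> q8[c] + 2 h[c]",
    "MQL8": "mql8[c] -> mqn8[c] + 2 h[c]",
    "2DMMQL8": "2dmmql8[c] -> 2dmmq8[c] + 2 h[c]",
    "ACCOA": "accoa[c] + h2o[c] -> ac[c] + coa[c] + h[c]",
    # electron unbalanced by design (no reductant for the 2-oxoglutarate step)
    "GLU": "glu__L[c] + h2o[c] -> akg[c] + nh4[c]",
    "HGRADIENT": "h[p] -> h[c]",
}

#: periplasm -> cytosol proton discharge; two-compartment models fall back to
#: the extracellular proton.
_HGRADIENT_FALLBACK = "h[e] -> h[c]"

COMPARTMENT_ALIASES = {
    "c": ("c", "c0", "cytosol", "cytoplasm", "in"),
    "p": ("p", "p0", "periplasm"),
    "e": ("e", "e0", "extracellular", "ext", "out"),
}

# Generic base id -> per-namespace identifier candidates, tried in order.
# ModelSEED cpd-ids and MetaNetX MNXM-ids are standard database identifiers;
# they are overridable defaults, not authoritative mappings.
_MODELSEED = {
    "atp": "cpd00002", "h2o": "cpd00001", "adp": "cpd00008", "pi": "cpd00009",
    "h": "cpd00067", "ctp": "cpd00052", "cdp": "cpd00096", "gtp": "cpd00038",
    "gdp": "cpd00031", "utp": "cpd00062", "udp": "cpd00014", "itp": "cpd00068",
    "idp": "cpd00090", "nadh": "cpd00004", "nad": "cpd00003",
    "nadph": "cpd00005", "nadp": "cpd00006", "fadh2": "cpd00982",
    "fad": "cpd00015", "fmnh2": "cpd01270", "fmn": "cpd00050",
    "q8h2": "cpd15561", "q8": "cpd15560", "mql8": "cpd15499",
    "mqn8": "cpd15500", "2dmmql8": "cpd15353", "2dmmq8": "cpd15352",
    "accoa": "cpd00022", "ac": "cpd00029", "coa": "cpd00010",
    "glu__L": "cpd00023", "akg": "cpd00024", "nh4": "cpd00013",
}
_METANETX = {
    "atp": "MNXM3", "h2o": "MNXM2", "adp": "MNXM7", "pi": "MNXM9",
    "h": "MNXM1", "ctp": "MNXM63", "cdp": "MNXM220", "gtp": "MNXM51",
    "gdp": "MNXM30", "utp": "MNXM78", "udp": "MNXM17", "itp": "MNXM423",
    "idp": "MNXM280", "nadh": "MNXM10", "nad": "MNXM8", "nadph": "MNXM6",
    "nadp": "MNXM5", "fadh2": "MNXM38", "fad": "MNXM33", "fmnh2": "MNXM208",
    "fmn": "MNXM119", "q8h2": "MNXM191", "q8": "MNXM232", "mql8": "MNXM510",
    "mqn8": "MNXM509", "2dmmql8": "MNXM727", "2dmmq8": "MNXM726",
    "accoa": "MNXM21", "ac": "MNXM26", "coa": "MNXM12",
    "glu__L": "MNXM89557", "akg": "MNXM20", "nh4": "MNXM15",
}

SYNONYMS: dict[str, dict[str, tuple[str, ...]]] = {
    "bigg": {"glu__L": ("glu__L", "glu_L", "glu-L")},
    "modelseed": {k: (v,) for k, v in _MODELSEED.items()},
    "metanetx": {k: (v,) for k, v in _METANETX.items()},
}
SYNONYMS["metanetx"]["glu__L"] = ("MNXM89557", "MNXM741")


def _parse_equation(eq: str) -> tuple[tuple[float, str, str], ...]:
    """Parse 'a[c] + 2 b[c] -> c[c]' into ((coef, base, role), ...)."""
    lhs, rhs = eq.split("->")
    terms = []
    for side, sign in ((lhs, -1.0), (rhs, 1.0)):
        for chunk in side.split("+"):
            chunk = chunk.strip()
            if not chunk:
                continue
            parts = chunk.split()
            coef = 1.0
            if len(parts) == 2:
                coef, chunk = float(parts[0]), parts[1]
            elif len(parts) != 1:
                raise ValueError(f"bad equation term {chunk!r}")
            else:
                chunk = parts[0]
            if chunk.endswith("]") and "[" in chunk:
                base, role = chunk[:-1].rsplit("[", 1)
            else:
                base, role = chunk, "c"
            terms.append((sign * coef, base, role))
    return tuple(terms)


@dataclass
class DissipationReaction:
    """One energy-dissipation reaction resolved against a concrete model."""
    label: str
    stoichiometry: dict[str, float]
    namespace: str
    integration: float
    active: bool
    missing: tuple[str, ...] = ()
    reaction_id: str | None = None


@dataclass
class DissipationCatalog:
    """(label, namespace) -> stoichiometry template.

    Exactly 15 labels per namespace.  ``from_tsv``/``to_tsv`` exchange the
    catalog as a three-column table (label, namespace, equation).
    """
    entries: dict[tuple[str, str], tuple[tuple[float, str, str], ...]] = \
        field(default_factory=dict)

    @classmethod
    def default(cls) -> "DissipationCatalog":
        entries = {}
        for ns in ("bigg", "modelseed", "metanetx"):
            for label, eq in _TEMPLATES.items():
                entries[(label, ns)] = _parse_equation(eq)
        return cls(entries)

    def labels(self, namespace: str) -> list[str]:
        return [lab for lab in LABELS if (lab, namespace) in self.entries]

    def to_tsv(self, path) -> None:
        lines = ["label\tnamespace\tequation"]
        for (label, ns), terms in self.entries.items():
            lhs = " + ".join(f"{-c:g} {b}[{r}]" if c != -1 else f"{b}[{r}]"
                             for c, b, r in terms if c < 0)
            rhs = " + ".join(f"{c:g} {b}[{r}]" if c != 1 else f"{b}[{r}]"
                             for c, b, r in terms if c > 0)
            lines.append(f"{label}\t{ns}\t{lhs} -> {rhs}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "DissipationCatalog":
        entries = {}
        for line in Path(path).read_text().splitlines()[1:]:
            if not line.strip():
                continue
            label, ns, eq = line.split("\t")
            entries[(label, ns)] = _parse_equation(eq)
        return cls(entries)


def resolve_metabolite(model: MetabolicModel, base: str,
                       role: str) -> str | None:
    """Find the model metabolite matching a template base id and compartment.

    Candidate raw ids come from the per-namespace synonym table (the base id
    itself is always tried).  A model metabolite matches if its id is the raw
    id suffixed with a compartment alias (``atp_c``, ``cpd00002_c0``,
    ``MNXM3[c]``) or if the bare id matches and the metabolite's declared
    compartment is an alias of the requested role.  Cytosol-preferred ordering
    is achieved by alias order within a role.
    """
    aliases = COMPARTMENT_ALIASES[role]
    raws = SYNONYMS.get(model.namespace, {}).get(base, ()) or (base,)
    if base not in raws:
        raws = tuple(raws) + (base,)
    best: tuple[int, int, str] | None = None
    for ri, raw in enumerate(raws):
        for met in model.metabolites.values():
            comp = (met.compartment or "").lower()
            rank = None
            for ai, alias in enumerate(aliases):
                if met.id in (f"{raw}_{alias}", f"{raw}[{alias}]"):
                    rank = (ri, ai, met.id)
                    break
            if rank is None and met.id == raw and comp in aliases:
                rank = (ri, aliases.index(comp), met.id)
            if rank is not None and (best is None or rank < best):
                best = rank
    return best[2] if best else None


def build_dissipation_reactions(
        model: MetabolicModel,
        catalog: DissipationCatalog | None = None) -> list[DissipationReaction]:
    """Resolve all 15 EDR templates against a model.

    The integration score is the fraction of the template's metabolites found
    in the model; an EDR with integration < 1 cannot carry any flux and is
    returned flagged inactive.
    """
    catalog = catalog or DissipationCatalog.default()
    out = []
    for label in LABELS:
        terms = catalog.entries.get((label, model.namespace))
        if terms is None:
            log.warning("catalog has no %s entry for namespace %s",
                        label, model.namespace)
            continue
        candidates = [terms]
        if label == "HGRADIENT":
            candidates.append(_parse_equation(_HGRADIENT_FALLBACK))
        best = None
        for cand in candidates:
            stoich: dict[str, float] = {}
            missing: list[str] = []
            for coef, base, role in cand:
                mid = resolve_metabolite(model, base, role)
                if mid is None:
                    missing.append(f"{base}[{role}]")
                else:
                    stoich[mid] = stoich.get(mid, 0.0) + coef
            integration = (len(cand) - len(missing)) / len(cand)
            dr = DissipationReaction(
                label=label, stoichiometry=stoich, namespace=model.namespace,
                integration=integration, active=not missing,
                missing=tuple(missing))
            if best is None or dr.integration > best.integration:
                best = dr
            if dr.active:
                break
        out.append(best)
    return out


def attach_dissipation(model: MetabolicModel,
                       drs: list[DissipationReaction]) -> MetabolicModel:
    """Return a copy of the model with the active EDRs added.

    EDRs are irreversible ([0, EDR_UPPER]), marked ``is_dissipation`` so the
    detection module exempts them from the internal flux clamp, and recorded
    in ``model.notes['edrs']``.  Attaching twice is an error.
    """
    if model.notes.get("edrs"):
        raise ValueError("dissipation reactions already attached")
    mm = model.copy()
    registry: dict[str, dict] = {}
    for dr in drs:
        rid = None
        if dr.active:
            rid = f"EDR_{dr.label}"
            while rid in mm.reactions:
                alias = rid + "_x"
                log.warning("EDR id %s collides with a model reaction; "
                            "renamed to %s", rid, alias)
                rid = alias
            mm.reactions[rid] = Reaction(
                id=rid, stoichiometry=dict(dr.stoichiometry),
                lower_bound=0.0, upper_bound=EDR_UPPER,
                name=f"{dr.label} energy dissipation",
                is_dissipation=True)
        registry[dr.label] = {
            "reaction_id": rid, "integration": dr.integration,
            "active": dr.active, "missing": list(dr.missing)}
    mm.notes["edrs"] = registry
    return mm


def detach_dissipation(model: MetabolicModel) -> MetabolicModel:
    """Inverse of :func:`attach_dissipation`."""
    mm = model.copy()
    mm.reactions = {rid: r for rid, r in mm.reactions.items()
                    if not r.is_dissipation}
    mm.notes.pop("edrs", None)
    return mm


def attach_default(model: MetabolicModel,
                   catalog: DissipationCatalog | None = None) -> MetabolicModel:
    """Convenience: build and attach the default EDR set in one step."""
    return attach_dissipation(model, build_dissipation_reactions(model, catalog))
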