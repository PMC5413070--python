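"""Small toy models with planted energy-generating cycles and known cuts.

Each named fixture reconstructs one of the classic EGC motifs observed in
published genome-scale reconstructions -- transporter proton-cost mismatches,
an erroneous NTP-charging isoenzyme pair, and a redox loop -- plus EGC-free
controls.  Every fixture carries a biomass reaction fed by a simple nutrient
pathway so viability is testable, and ships with ground truth (planted cycle
membership, minimal cut size) that the test suite re-derives by brute force.

The reconstructions are qualitative: reaction ids echo the database reactions
that inspired them, but stoichiometries are the simplest proton-consistent
forms that reproduce the documented cycle behavior (e.g. ATP synthase is the
standard ``4 h[p] + adp + pi -> atp + h2o + 3 h[c]``, which yields 0.25 ATP
per unit of cycle flux in the malate/sodium triangle).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import MetabolicModel, Metabolite, Reaction


@dataclass
class PlantedEGC:
    label: str
    members: frozenset            # reaction ids incl. the EDR
    expected_optimum: float       # detection optimum under unit clamps
    min_cut_size: int
    n_min_cuts: int | None = None  # alternative minimal cuts (unprotected)


@dataclass
class FixtureSpec:
    name: str
    description: str
    planted_egcs: list[PlantedEGC] = field(default_factory=list)
    viable: bool = True
    overall_min_cut: int = 0      # removals eliminating *all* planted cycles


def _model(model_id, mets, rxns, biomass="BIOMASS") -> MetabolicModel:
    metabolites = {}
    for mid, comp in mets:
        metabolites[mid] = Metabolite(id=mid, compartment=comp)
    reactions = {}
    for entry in rxns:
        rid, stoich, lo, hi = entry[:4]
        kw = entry[4] if len(entry) > 4 else {}
        reactions[rid] = Reaction(id=rid, stoichiometry=dict(stoich),
                                  lower_bound=float(lo), upper_bound=float(hi),
                                  **kw)
    m = MetabolicModel(id=model_id, metabolites=metabolites,
                       reactions=reactions, biomass_reaction_id=biomass,
                       namespace="bigg")
    m.validate()
    return m


def _scaffold():
    """Shared nutrient pathway: glucose exchange + transporter."""
    mets = [("glc_e", "e"), ("glc_c", "c")]
    rxns = [
        ("EX_glc", {"glc_e": -1}, -10, 1000, {"is_exchange": True}),
        ("GLCt", {"glc_e": -1, "glc_c": 1}, 0, 1000),
    ]
    return mets, rxns


_C = [(m, "c") for m in ()]   # placeholder to keep builders uniform


def _fig2():
    """Symporter exports a metabolite plus a proton; a uniporter re-imports
    the metabolite alone.  Together they pump protons for free."""
    mets, rxns = _scaffold()
    mets += [("a_c", "c"), ("a_e", "e"), ("h_c", "c"), ("h_e", "e")]
    rxns += [
        ("SYMt", {"a_c": -1, "h_c": -1, "a_e": 1, "h_e": 1}, -1000, 1000),
        ("UNIt", {"a_e": -1, "a_c": 1}, -1000, 1000),
        ("BIOMASS", {"glc_c": -1}, 0, 1000),
    ]
    spec = FixtureSpec(
        name="fig2",
        description="hypothetical symporter/uniporter proton-gradient cycle",
        planted_egcs=[PlantedEGC("HGRADIENT",
                                 frozenset({"SYMt", "UNIt", "EDR_HGRADIENT"}),
                                 1.0, 1, 2)],
        overall_min_cut=1)
    return _model("fig2", mets, rxns), spec


def _fig6a():
    """Malate/2H+ symporter + malate/Na+ symporter + Na+/H+ antiporter leave
    one periplasmic proton per turn; ATP synthase converts four of them into
    one ATP (detection optimum 0.25 under unit clamps)."""
    mets, rxns = _scaffold()
    mets += [("mal_c", "c"), ("mal_p", "p"), ("na1_c", "c"), ("na1_p", "p"),
             ("h_c", "c"), ("h_p", "p"), ("atp_c", "c"), ("adp_c", "c"),
             ("pi_c", "c"), ("h2o_c", "c")]
    rxns += [
        ("MALt2rpp", {"mal_c": -1, "h_c": -2, "mal_p": 1, "h_p": 2},
         -1000, 1000),
        ("MALNAt", {"mal_p": -1, "na1_p": -1, "mal_c": 1, "na1_c": 1},
         -1000, 1000),
        ("NAt3pp", {"na1_c": -1, "h_p": -1, "na1_p": 1, "h_c": 1},
         -1000, 1000),
        ("ATPS4rpp", {"adp_c": -1, "pi_c": -1, "h_p": -4,
                      "atp_c": 1, "h2o_c": 1, "h_c": 3}, -1000, 1000,
         {"name": "ATP synthase"}),
        ("BIOMASS", {"glc_c": -1}, 0, 1000),
    ]
    triangle = {"MALt2rpp", "MALNAt", "NAt3pp"}
    spec = FixtureSpec(
        name="fig6a",
        description="malate/sodium/proton transporter triangle + ATP synthase",
        planted_egcs=[
            PlantedEGC("ATP", frozenset(triangle | {"ATPS4rpp", "EDR_ATP"}),
                       0.25, 1, None),
            PlantedEGC("HGRADIENT", frozenset(triangle | {"EDR_HGRADIENT"}),
                       1.0, 1, 3),
        ],
        overall_min_cut=1)
    return _model("fig6a", mets, rxns), spec


def _fig6b():
    """Tartrate facilitated import + three antiport/symport steps establish a
    periplasmic proton gradient (one proton per symport step)."""
    mets, rxns = _scaffold()
    mets += [("tartr_c", "c"), ("tartr_p", "p"), ("succ_c", "c"),
             ("succ_p", "p"), ("asp_c", "c"), ("asp_p", "p"),
             ("h_c", "c"), ("h_p", "p")]
    rxns += [
        ("TARTRtpp", {"tartr_p": -1, "tartr_c": 1}, -1000, 1000),
        ("TARTRt7pp", {"tartr_c": -1, "succ_p": -1, "tartr_p": 1,
                       "succ_c": 1}, -1000, 1000),
        ("SUCASPtpp", {"succ_c": -1, "asp_p": -1, "succ_p": 1, "asp_c": 1},
         -1000, 1000),
        ("ASPt2pp", {"asp_c": -1, "h_c": -1, "asp_p": 1, "h_p": 1},
         -1000, 1000),
        ("BIOMASS", {"glc_c": -1}, 0, 1000),
    ]
    members = {"TARTRtpp", "TARTRt7pp", "SUCASPtpp", "ASPt2pp",
               "EDR_HGRADIENT"}
    spec = FixtureSpec(
        name="fig6b",
        description="tartrate/succinate/aspartate transporter chain",
        planted_egcs=[PlantedEGC("HGRADIENT", frozenset(members), 1.0, 1, 4)],
        overall_min_cut=1)
    return _model("fig6b", mets, rxns), spec


def _fig6c():
    """NADH:menaquinone oxidoreductase pumps protons; a four-enzyme chain
    erroneously regenerates NADH and menaquinone, closing a loop that nets
    three periplasmic protons per turn."""
    mets, rxns = _scaffold()
    mets += [(m, "c") for m in
             ("nadh_c", "nad_c", "mqn8_c", "mql8_c", "aox_c", "ared_c",
              "box_c", "bred_c", "cox_c", "cred_c", "h_c")]
    mets += [("h_p", "p")]
    rxns += [
        ("NADH17pp", {"nadh_c": -1, "mqn8_c": -1, "h_c": -4,
                      "nad_c": 1, "mql8_c": 1, "h_p": 3}, 0, 1000),
        ("CYTOX1", {"mql8_c": -1, "aox_c": -1, "mqn8_c": 1, "ared_c": 1,
                    "h_c": 2}, -1000, 1000),
        ("ETC2", {"ared_c": -1, "box_c": -1, "aox_c": 1, "bred_c": 1},
         -1000, 1000),
        ("ETC3", {"bred_c": -1, "cox_c": -1, "box_c": 1, "cred_c": 1},
         -1000, 1000),
        ("NADRED", {"cred_c": -1, "nad_c": -1, "h_c": -1, "cox_c": 1,
                    "nadh_c": 1}, -1000, 1000),
        ("BIOMASS", {"glc_c": -1}, 0, 1000),
    ]
    members = {"NADH17pp", "CYTOX1", "ETC2", "ETC3", "NADRED",
               "EDR_HGRADIENT"}
    spec = FixtureSpec(
        name="fig6c",
        description="NADH:menaquinone oxidoreductase loop closed by a "
                    "four-enzyme chain",
        planted_egcs=[PlantedEGC("HGRADIENT", frozenset(members), 3.0, 1, 5)],
        overall_min_cut=1)
    return _model("fig6c", mets, rxns), spec


def _fig6d():
    """Adenosine-5'-phosphosulfate cycle: one sulfate adenylyltransferase
    forms APS from ATP + sulfate; an 'equivalent' reverse enzyme regenerates
    the ATP but charges a GTP as well.  One GTP appears per turn."""
    mets, rxns = _scaffold()
    mets += [(m, "c") for m in
             ("atp_c", "so4_c", "aps_c", "ppi_c", "gdp_c", "gtp_c",
              "pi_c", "h_c", "h2o_c")]
    rxns += [
        ("SADT", {"atp_c": -1, "so4_c": -1, "aps_c": 1, "ppi_c": 1},
         0, 1000),
        ("SADT2", {"aps_c": -1, "ppi_c": -1, "gdp_c": -1, "pi_c": -1,
                   "h_c": -1, "atp_c": 1, "gtp_c": 1, "so4_c": 1,
                   "h2o_c": 1}, 0, 1000),
        ("BIOMASS", {"glc_c": -1}, 0, 1000),
    ]
    spec = FixtureSpec(
        name="fig6d",
        description="APS-forming/APS-consuming isoenzyme pair charging GTP",
        planted_egcs=[PlantedEGC("GTP",
                                 frozenset({"SADT", "SADT2", "EDR_GTP"}),
                                 1.0, 1, 2)],
        overall_min_cut=1)
    return _model("fig6d", mets, rxns), spec


def _viable_control():
    """EGC-free control with a real ATP-producing pathway, so the ATP EDR is
    fully integrated yet cannot carry flux with exchanges closed."""
    mets, rxns = _scaffold()
    mets += [(m, "c") for m in
             ("pyr_c", "atp_c", "adp_c", "pi_c", "h_c", "h2o_c")]
    rxns += [
        ("GLYC", {"glc_c": -1, "adp_c": -2, "pi_c": -2, "h_c": -2,
                  "pyr_c": 2, "atp_c": 2, "h2o_c": 2}, 0, 1000),
        ("BIOMASS", {"pyr_c": -1, "atp_c": -1, "h2o_c": -1,
                     "adp_c": 1, "pi_c": 1, "h_c": 1}, 0, 1000),
    ]
    spec = FixtureSpec(name="viable_control",
                       description="EGC-free viable control", viable=True,
                       overall_min_cut=0)
    return _model("viable_control", mets, rxns), spec


def _two_pathway_biomass():
    """Biomass fed both by a capacity-limited catabolic ATP source and by an
    erroneous ATP-charging pair; eliminating the cycle drops the optimum."""
    mets, rxns = _scaffold()
    mets += [(m, "c") for m in
             ("x_c", "y_c", "atp_c", "adp_c", "pi_c", "h_c", "h2o_c")]
    rxns += [
        ("CATAB", {"glc_c": -1, "adp_c": -1, "pi_c": -1, "h_c": -1,
                   "atp_c": 1, "h2o_c": 1}, 0, 50),
        ("CYC1", {"x_c": -1, "y_c": 1}, -1000, 1000),
        ("CYC2", {"y_c": -1, "adp_c": -1, "pi_c": -1, "h_c": -1,
                  "x_c": 1, "atp_c": 1, "h2o_c": 1}, -1000, 1000),
        ("BIOMASS", {"glc_c": -1, "atp_c": -1, "h2o_c": -1,
                     "adp_c": 1, "pi_c": 1, "h_c": 1}, 0, 1000),
    ]
    spec = FixtureSpec(
        name="two_pathway_biomass",
        description="biomass fed by EGC-derived ATP plus a capped pathway",
        planted_egcs=[PlantedEGC("ATP",
                                 frozenset({"CYC1", "CYC2", "EDR_ATP"}),
                                 1.0, 1, 2)],
        overall_min_cut=1)
    return _model("two_pathway_biomass", mets, rxns), spec


def _disjoint_double_fig6d():
    """Two reaction-disjoint APS cycles sharing the GTP pool: the detection
    optimum doubles and the minimal cut needs one removal per cycle."""
    model, _ = _fig6d()
    for mid in ("atp2_c", "so42_c", "aps2_c", "ppi2_c"):
        model.metabolites[mid] = Metabolite(id=mid, compartment="c")
    model.reactions["SADTB"] = Reaction(
        id="SADTB", stoichiometry={"atp2_c": -1, "so42_c": -1,
                                   "aps2_c": 1, "ppi2_c": 1},
        lower_bound=0, upper_bound=1000)
    model.reactions["SADT2B"] = Reaction(
        id="SADT2B", stoichiometry={"aps2_c": -1, "ppi2_c": -1, "gdp_c": -1,
                                    "pi_c": -1, "h_c": -1, "atp2_c": 1,
                                    "gtp_c": 1, "so42_c": 1, "h2o_c": 1},
        lower_bound=0, upper_bound=1000)
    model.id = "disjoint_double_fig6d"
    spec = FixtureSpec(
        name="disjoint_double_fig6d",
        description="two disjoint APS cycles sharing one GTP pool",
        planted_egcs=[
            PlantedEGC("GTP", frozenset({"SADT", "SADT2", "EDR_GTP"}),
                       2.0, 2, None)],
        overall_min_cut=2)
    return model, spec


_BUILDERS = {
    "fig2": _fig2,
    "fig6a": _fig6a,
    "fig6b": _fig6b,
    "fig6c": _fig6c,
    "fig6d": _fig6d,
    "viable_control": _viable_control,
    "two_pathway_biomass": _two_pathway_biomass,
    "disjoint_double_fig6d": _disjoint_double_fig6d,
}

FIXTURE_NAMES = tuple(_BUILDERS)


def make_fixture(name: str):
    """Return (model, ground-truth spec) for a named fixture."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(_BUILDERS)}"
        ) from None
    return builder()


def make_random_egc_model(n_reactions: int = 30, n_planted: int = 1,
                          seed: int = 0, motifs: str = "mixed"):
    """Random viable model with ``n_planted`` disjoint EGC motifs.

    A linear irreversible nutrient backbone (provably acyclic, hence EGC-free
    on its own) is decorated with random forward branch reactions and with
    planted motifs: an ATP-charging isoenzyme pair (``motifs='atp'``), a
    proton symporter/uniporter mismatch (``'proton'``), or alternating kinds
    (``'mixed'``).  Deterministic under ``seed``.
    """
    if n_reactions > 60:
        raise ValueError("n_reactions must be <= 60 to keep the brute-force "
                         "oracle tractable")
    rng = np.random.default_rng(seed)
    mets: list[tuple[str, str]] = [("nut_e", "e")]
    rxns: list = [("EX_nut", {"nut_e": -1}, -10, 1000,
                   {"is_exchange": True})]
    chain_len = max(3, min(8, n_reactions // 3))
    for i in range(chain_len):
        mets.append((f"m{i}_c", "c"))
    rxns.append(("TNUT", {"nut_e": -1, "m0_c": 1}, 0, 1000))
    for i in range(chain_len - 1):
        rxns.append((f"CH{i}", {f"m{i}_c": -1, f"m{i + 1}_c": 1}, 0, 1000))
    rxns.append(("BIOMASS", {f"m{chain_len - 1}_c": -1}, 0, 1000))

    # cofactor pool shared by ATP motifs (and by the ATP EDR)
    mets += [(m, "c") for m in ("atp_c", "adp_c", "pi_c", "h_c", "h2o_c")]

    planted: list[PlantedEGC] = []
    n_atp = n_h = 0
    kinds = {"atp": ["atp"], "proton": ["proton"],
             "mixed": ["atp", "proton"]}[motifs]
    have_h_e = False
    for k in range(n_planted):
        kind = kinds[k % len(kinds)]
        if kind == "atp":
            n_atp += 1
            mets += [(f"x{k}_c", "c"), (f"y{k}_c", "c")]
            rxns += [
                (f"AEGC{k}a", {f"x{k}_c": -1, f"y{k}_c": 1}, -1000, 1000),
                (f"AEGC{k}b", {f"y{k}_c": -1, "adp_c": -1, "pi_c": -1,
                               "h_c": -1, f"x{k}_c": 1, "atp_c": 1,
                               "h2o_c": 1}, -1000, 1000),
            ]
        else:
            n_h += 1
            if not have_h_e:
                mets.append(("h_e", "e"))
                have_h_e = True
            mets += [(f"w{k}_c", "c"), (f"w{k}_e", "e")]
            rxns += [
                (f"PEGC{k}a", {f"w{k}_c": -1, "h_c": -1, f"w{k}_e": 1,
                               "h_e": 1}, -1000, 1000),
                (f"PEGC{k}b", {f"w{k}_e": -1, f"w{k}_c": 1}, -1000, 1000),
            ]
    if n_atp:
        planted.append(PlantedEGC(
            "ATP",
            frozenset(r for k in range(n_planted) for r in
                      (f"AEGC{k}a", f"AEGC{k}b") if f"AEGC{k}a" in
                      {e[0] for e in rxns}) | {"EDR_ATP"},
            float(n_atp), n_atp, None))
    if n_h:
        planted.append(PlantedEGC(
            "HGRADIENT",
            frozenset(r for k in range(n_planted) for r in
                      (f"PEGC{k}a", f"PEGC{k}b") if f"PEGC{k}a" in
                      {e[0] for e in rxns}) | {"EDR_HGRADIENT"},
            float(n_h), n_h, None))

    # fill the reaction budget with random forward branches (keeps the
    # backbone acyclic: edges always run toward higher chain indices)
    n_branch = max(0, n_reactions - len(rxns))
    for b in range(n_branch):
        i = int(rng.integers(0, chain_len - 1))
        j = int(rng.integers(i + 1, chain_len))
        rxns.append((f"BR{b}", {f"m{i}_c": -1, f"m{j}_c": 1}, 0, 1000))

    model = _model(f"random_s{seed}_p{n_planted}", mets, rxns)
    spec = FixtureSpec(
        name=model.id,
        description="random acyclic backbone with planted EGC motifs",
        planted_egcs=planted, viable=True,
        overall_min_cut=n_planted)
    return model, spec
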