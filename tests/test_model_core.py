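"""Model loading, normalization, viability and balance checking."""
import math

import pytest
from hypothesis import given, strategies as st

import egctools as egc
from egctools.model_core import (ModelError, Metabolite, Reaction,
                                 model_from_dict, model_to_dict,
                                 parse_formula)
from egctools.fixtures import FIXTURE_NAMES, make_fixture


def _tiny(reactions, mets=None, biomass="BIOMASS", namespace="bigg"):
    metabolites = {m: Metabolite(id=m, compartment=m.rsplit("_", 1)[-1])
                   for m in (mets or sorted(
                       {k for r in reactions.values()
                        for k in r.stoichiometry}))}
    m = egc.MetabolicModel(id="tiny", metabolites=metabolites,
                           reactions=reactions, biomass_reaction_id=biomass,
                           namespace=namespace)
    m.validate()
    return m


# ---------------------------------------------------------------- round trips

@pytest.mark.parametrize("name", FIXTURE_NAMES)
def test_sbml_round_trip_preserves_model(name, tmp_path):
    model, _ = make_fixture(name)
    path = tmp_path / f"{name}.xml"
    egc.save_sbml(model, path)
    loaded = egc.load_model(path)
    assert loaded.namespace == model.namespace
    assert loaded.biomass_reaction_id == model.biomass_reaction_id
    assert set(loaded.reactions) == set(model.reactions)
    for rid, r in model.reactions.items():
        r2 = loaded.reactions[rid]
        assert r2.stoichiometry == r.stoichiometry
        assert (r2.lower_bound, r2.upper_bound) == \
               (r.lower_bound, r.upper_bound)
        assert r2.is_exchange == r.is_exchange


def test_json_round_trip_identity():
    model, _ = make_fixture("fig6d")
    clone = model_from_dict(model_to_dict(model))
    assert model_to_dict(clone) == model_to_dict(model)


def test_dangling_metabolite_reported_by_id():
    doc = model_to_dict(make_fixture("fig6d")[0])
    doc["reactions"][2]["stoichiometry"]["ghost_c"] = -1.0
    with pytest.raises(ModelError, match="ghost_c"):
        model_from_dict(doc)


def test_missing_biomass_names_heuristic():
    doc = {"id": "m", "namespace": "bigg",
           "metabolites": [{"id": "a_c", "compartment": "c"}],
           "reactions": [{"id": "R1", "stoichiometry": {"a_c": 1.0},
                          "lower_bound": 0, "upper_bound": 1}]}
    with pytest.raises(ModelError, match="biomass"):
        model_from_dict(doc)


def test_fbc_bounds_passthrough(tmp_path):
    model, _ = make_fixture("fig6a")
    path = tmp_path / "m.xml"
    egc.save_sbml(model, path)
    loaded = egc.load_sbml(path)
    assert loaded.reactions["MALt2rpp"].lower_bound == -1000
    assert loaded.reactions["MALt2rpp"].upper_bound == 1000


# ---------------------------------------------------------------- normalize

def _with_atpm(lb=8.39):
    model, _ = make_fixture("viable_control")
    model.reactions["ATPM"] = Reaction(
        id="ATPM", stoichiometry={"atp_c": -1, "h2o_c": -1, "adp_c": 1,
                                  "pi_c": 1, "h_c": 1},
        lower_bound=lb, upper_bound=1000, name="ATP maintenance")
    return model


def test_atpm_lower_bound_zeroed():
    model = _with_atpm(8.39)
    normalized, log = egc.normalize_model(model)
    assert normalized.reactions["ATPM"].lower_bound == 0.0
    assert any(e["change"] == "atpm_lower_bound_zeroed" and
               e["reaction"] == "ATPM" for e in log)


def test_exchange_uptake_convention_flipped():
    model, _ = make_fixture("viable_control")
    ex = model.reactions["EX_glc"]
    ex.stoichiometry = {"glc_e": 1.0}       # written as "-> glc[e]"
    ex.lower_bound, ex.upper_bound = 0.0, 10.0
    before = egc.check_viability(model)[1]
    normalized, log = egc.normalize_model(model)
    ex2 = normalized.reactions["EX_glc"]
    assert ex2.stoichiometry == {"glc_e": -1.0}
    assert (ex2.lower_bound, ex2.upper_bound) == (-10.0, 0.0)
    assert any(e["change"] == "exchange_direction_flipped" for e in log)
    # the flux polytope is unchanged up to the recorded sign relabeling
    assert egc.check_viability(normalized)[1] == pytest.approx(before)


def test_normalize_idempotent():
    model = _with_atpm()
    once, log1 = egc.normalize_model(model)
    twice, log2 = egc.normalize_model(once)
    assert log1 and not log2
    assert model_to_dict(twice) == model_to_dict(once)


# ---------------------------------------------------------------- viability

def test_viable_control_optimum_matches_hand_value():
    model, _ = make_fixture("viable_control")
    viable, opt = egc.check_viability(model)
    # biomass upper bound (1000) binds before the opened uptake does
    assert viable and opt == pytest.approx(1000.0, abs=1e-6)


def test_disconnected_biomass_precursor_not_viable():
    rxns = {
        "EX_a": Reaction("EX_a", {"a_e": -1}, -10, 1000, is_exchange=True),
        "BIOMASS": Reaction("BIOMASS", {"orphan_c": -1}, 0, 1000),
    }
    model = _tiny(rxns)
    viable, opt = egc.check_viability(model)
    assert not viable and opt == pytest.approx(0.0, abs=1e-9)
    assert egc.check_viability(model, threshold=0.0)[0]   # v=0 is feasible


@pytest.mark.parametrize("name", ["viable_control", "fig6d"])
def test_viability_monotone_in_threshold(name):
    model, _ = make_fixture(name)
    _, opt = egc.check_viability(model)
    verdicts = [egc.check_viability(model, threshold=t)[0]
                for t in (0.0, 1e-6, 1.0, opt, opt * 2 + 1)]
    # once False at some threshold, False at every larger one
    assert verdicts == sorted(verdicts, reverse=True)


# ---------------------------------------------------------------- balance

_FORMULAS = {"atp_c": ("C10H16N5O13P3", 0), "adp_c": ("C10H15N5O10P2", 0),
             "pi_c": ("H3PO4", 0), "h_c": ("H", 1), "h2o_c": ("H2O", 0)}


def _balance_model(stoich):
    mets = {m: Metabolite(id=m, compartment="c", formula=_FORMULAS[m][0],
                          charge=_FORMULAS[m][1]) for m in _FORMULAS}
    rxns = {"R": Reaction("R", stoich, 0, 1000),
            "BIOMASS": Reaction("BIOMASS", {"atp_c": -1}, 0, 1000)}
    return egc.MetabolicModel("b", mets, rxns, "BIOMASS", "bigg")


def test_atp_hydrolysis_is_balanced():
    # neutral formulas: ATP + H2O -> ADP + H3PO4 (mass balance, charge +-0
    # when the proton is folded into the phosphate)
    model = _balance_model({"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1})
    finding = [f for f in egc.check_balance(model) if f.reaction_id == "R"][0]
    assert finding.balanced and not finding.element_deltas


def test_atp_to_adp_missing_phosphate_group():
    model = _balance_model({"atp_c": -1, "adp_c": 1})
    finding = [f for f in egc.check_balance(model) if f.reaction_id == "R"][0]
    assert finding.balanced is False
    assert finding.element_deltas["P"] == pytest.approx(-1)
    assert finding.element_deltas["O"] == pytest.approx(-3)
    assert finding.element_deltas["H"] == pytest.approx(-1)


def test_no_formulas_all_skipped():
    model, _ = make_fixture("viable_control")
    findings = egc.check_balance(model)
    assert findings and all(f.skipped == "no formula" for f in findings)


@given(st.lists(st.tuples(st.sampled_from(["C", "H", "O", "N", "P", "Fe",
                                           "Mg", "Zn"]),
                          st.integers(1, 40)),
                min_size=1, max_size=6, unique_by=lambda t: t[0]))
def test_formula_parser_reconstructs_counts(parts):
    formula = "".join(f"{el}{n if n > 1 else ''}" for el, n in parts)
    assert parse_formula(formula) == dict(parts)


def test_unparseable_formula_rejected():
    for bad in ("", "h2o", "C6(H12)O6", "X!"):
        with pytest.raises(ValueError):
            parse_formula(bad)
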