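"""Bi-level correction: optimality, alternatives, protection, certificates."""
import math

import numpy as np
import pytest

import egctools as egc
from egctools import correct as C
from egctools.model_core import Metabolite, Reaction, biomass_optimum

from conftest import prepared_fixture


def _solve(name, protect_atp_synthase=False, weights=None, k=1):
    model, spec = prepared_fixture(name)
    cands = C.split_reversibles(model, weights=weights,
                                protect_atp_synthase=protect_atp_synthase)
    program = C.build_bilevel(model, cands)
    if k > 1:
        sols = C.enumerate_alternatives(program, k)
        return model, cands, program, sols
    return model, cands, program, [C.solve_correction(program)]


def test_split_reversibles_directions():
    model, _ = prepared_fixture("fig6a")
    cands = C.split_reversibles(model)
    by_rxn = {}
    for c in cands:
        by_rxn.setdefault(c.reaction_id, set()).add(c.direction)
    assert by_rxn["MALt2rpp"] == {"forward", "backward"}   # reversible
    assert by_rxn["BIOMASS"] == {"forward"}                # irreversible
    # EDRs and exchanges are never candidates
    assert not any(model.reactions[c.reaction_id].is_dissipation or
                   model.reactions[c.reaction_id].is_exchange for c in cands)


def test_fig6d_yields_exactly_two_alternative_cuts():
    _, _, _, sols = _solve("fig6d", k=5)
    assert len(sols) == 2
    assert {frozenset(s.removals) for s in sols} == {
        frozenset({("SADT", "forward")}),
        frozenset({("SADT2", "forward")})}
    assert all(s.objective == pytest.approx(1.0) for s in sols)


def test_fig6a_protected_cut_excludes_synthase():
    model, cands, _, sols = _solve("fig6a", protect_atp_synthase=True)
    sol = sols[0]
    assert sol.objective == pytest.approx(1.0)
    assert len(sol.removals) == 1
    assert all(rid != "ATPS4rpp" for rid, _ in sol.removals)
    # the cut must break the transporter triangle
    assert next(iter(sol.removals)) in {
        ("MALt2rpp", "forward"), ("MALNAt", "forward"), ("NAt3pp", "forward")}


def test_fig6a_unprotected_alternatives_are_all_triangle_cuts():
    _, _, _, sols = _solve("fig6a", k=10)
    assert {next(iter(s.removals)) for s in sols} == {
        ("MALt2rpp", "forward"), ("MALNAt", "forward"), ("NAt3pp", "forward")}


def test_egc_free_model_needs_no_removals():
    _, _, _, sols = _solve("viable_control")
    sol = sols[0]
    assert sol.removals == frozenset() and sol.objective == 0.0
    assert sol.certified_egc_free
    assert sol.biomass_after == pytest.approx(sol.biomass_before)


def test_all_binaries_zero_infeasible_iff_egcs_present():
    for name, feasible in (("fig6d", False), ("viable_control", True)):
        model, _ = prepared_fixture(name)
        cands = C.split_reversibles(model)
        program = C.build_bilevel(model, cands)
        res = C.solve_milp(program, fixed_delta=np.zeros(len(cands)))
        assert (res.status != 2) == feasible


def test_certificates_hold_on_every_solution():
    for name in ("fig6d", "fig6a", "fig6b", "fig6c", "two_pathway_biomass",
                 "disjoint_double_fig6d"):
        model, cands, program, sols = _solve(name, k=6)
        for sol in sols:
            assert sol.certified_egc_free
            assert sol.biomass_after >= program.T_g - 1e-6
            assert sol.biomass_after <= sol.biomass_before + 1e-6
            constrained = C.apply_removals(model, sol.removals)
            report = egc.detect_egc(constrained)
            assert all(t.optimum <= 1e-6 for t in report.results.values())


def test_removals_constrain_bounds_never_delete():
    model, _, _, sols = _solve("fig6d")
    constrained = C.apply_removals(model, sols[0].removals)
    assert set(constrained.reactions) == set(model.reactions)
    for rid, direction in sols[0].removals:
        r = constrained.reactions[rid]
        assert (r.upper_bound == 0.0) if direction == "forward" \
            else (r.lower_bound == 0.0)


def test_growth_threshold_above_optimum_is_config_error():
    model, _ = prepared_fixture("fig6d")
    cands = C.split_reversibles(model)
    with pytest.raises(C.ConfigurationError, match="exceeds"):
        C.build_bilevel(model, cands, T_g=5000.0)


def test_no_removal_only_correction_detected():
    """Biomass fed solely by EGC-derived ATP: no removal set can eliminate
    the cycle and preserve growth, so the solver must report infeasibility."""
    mets = {m: Metabolite(id=m, compartment=m.rsplit("_", 1)[-1])
            for m in ("glc_e", "glc_c", "x_c", "y_c", "atp_c", "adp_c",
                      "pi_c", "h_c", "h2o_c")}
    rxns = {
        "EX_glc": Reaction("EX_glc", {"glc_e": -1}, -10, 1000,
                           is_exchange=True),
        "GLCt": Reaction("GLCt", {"glc_e": -1, "glc_c": 1}, 0, 1000),
        "CYC1": Reaction("CYC1", {"x_c": -1, "y_c": 1}, -1000, 1000),
        "CYC2": Reaction("CYC2", {"y_c": -1, "adp_c": -1, "pi_c": -1,
                                  "h_c": -1, "x_c": 1, "atp_c": 1,
                                  "h2o_c": 1}, -1000, 1000),
        "BIOMASS": Reaction("BIOMASS", {"glc_c": -1, "atp_c": -1,
                                        "h2o_c": -1, "adp_c": 1, "pi_c": 1,
                                        "h_c": 1}, 0, 1000),
    }
    model = egc.MetabolicModel("egc_fed", mets, rxns, "BIOMASS", "bigg")
    attached = egc.attach_default(model)
    cands = C.split_reversibles(attached)
    program = C.build_bilevel(attached, cands)
    with pytest.raises(C.InfeasibleCorrectionError):
        C.solve_correction(program)


def _synthase_toy():
    """EGC through a reaction that matches the ATP-synthase patterns, with
    weights making the synthase the cheapest simple cut."""
    mets = {m: Metabolite(id=m, compartment=m.rsplit("_", 1)[-1])
            for m in ("glc_e", "glc_c", "x_c", "y_c", "atp_c", "adp_c",
                      "pi_c", "h_c", "h2o_c")}
    rxns = {
        "EX_glc": Reaction("EX_glc", {"glc_e": -1}, -10, 1000,
                           is_exchange=True),
        "GLCt": Reaction("GLCt", {"glc_e": -1, "glc_c": 1}, 0, 1000),
        "GADGET": Reaction("GADGET", {"x_c": -1, "y_c": 1}, -1000, 1000),
        "ATPS4r": Reaction("ATPS4r", {"y_c": -1, "adp_c": -1, "pi_c": -1,
                                      "h_c": -1, "x_c": 1, "atp_c": 1,
                                      "h2o_c": 1}, -1000, 1000,
                           name="ATP synthase"),
        "BIOMASS": Reaction("BIOMASS", {"glc_c": -1}, 0, 1000),
    }
    model = egc.MetabolicModel("synthase_toy", mets, rxns, "BIOMASS", "bigg")
    return egc.attach_default(model)


def test_two_pass_avoids_protected_synthase():
    attached = _synthase_toy()
    weights = {"GADGET": 2.0, "ATPS4r": 1.0, "GLCt": 5.0, "BIOMASS": 5.0}
    simple, synthase = C.run_two_pass(attached, weights=weights)
    assert simple.removals == frozenset({("ATPS4r", "forward")})
    assert synthase.removals == frozenset({("GADGET", "forward")})
    assert synthase.objective > simple.objective   # protection costs weight


def test_two_pass_without_synthase_match_warns_and_repeats():
    model, _ = prepared_fixture("fig6d")
    simple, synthase = C.run_two_pass(model)
    assert simple.removals == synthase.removals


def test_protection_respected_everywhere():
    attached = _synthase_toy()
    cands = C.split_reversibles(attached, protect_atp_synthase=True)
    protected = {(c.reaction_id, c.direction) for c in cands if c.protected}
    assert protected
    sols = C.enumerate_alternatives(C.build_bilevel(attached, cands), 10)
    for sol in sols:
        assert not (sol.removals & protected)


def test_doubling_a_weight_never_decreases_objective():
    for name in ("fig6d", "fig6a", "two_pathway_biomass"):
        base = _solve(name)[3][0].objective
        model, _ = prepared_fixture(name)
        cands = C.split_reversibles(model)
        for cand in cands[:4]:
            weights = {(cand.reaction_id, cand.direction): 2.0}
            bumped = C.solve_correction(C.build_bilevel(
                model, C.split_reversibles(model, weights=weights)))
            assert bumped.objective >= base - 1e-9


def test_biomass_impact_ratio():
    _, _, _, sols = _solve("two_pathway_biomass")
    model, _ = prepared_fixture("two_pathway_biomass")
    ratio = C.biomass_impact(model, sols[0])
    # rich-medium optimum 1000 collapses to the capped pathway's 50
    assert ratio == pytest.approx(0.05, abs=1e-6)
    _, _, _, csols = _solve("viable_control")
    assert C.biomass_impact(model, csols[0]) == pytest.approx(1.0)


def test_biomass_impact_undefined_for_zero_baseline():
    sol = C.RemovalSolution(frozenset(), 0.0, 0.0, 0.0, True)
    model, _ = prepared_fixture("viable_control")
    assert math.isnan(C.biomass_impact(model, sol))


def test_enumerate_alternatives_k1_returns_single_optimum():
    _, _, program, _ = _solve("fig6a")
    sols = C.enumerate_alternatives(program, 1)
    assert len(sols) == 1 and sols[0].objective == pytest.approx(1.0)
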