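"""Energy-dissipation reaction construction, resolution and attachment."""
import pytest

import egctools as egc
from egctools.dissipation import (LABELS, DissipationCatalog,
                                  build_dissipation_reactions,
                                  attach_dissipation, detach_dissipation)
from egctools.fixtures import make_fixture
from egctools.model_core import (MetabolicModel, Metabolite, Reaction,
                                 model_to_dict)


def test_catalog_has_15_labels_per_namespace():
    cat = DissipationCatalog.default()
    for ns in ("bigg", "modelseed", "metanetx"):
        assert cat.labels(ns) == list(LABELS)
        assert len(cat.labels(ns)) == 15


def test_atp_edr_stoichiometry_bigg():
    model, _ = make_fixture("viable_control")
    drs = {d.label: d for d in build_dissipation_reactions(model)}
    atp = drs["ATP"]
    assert atp.active and atp.integration == 1.0
    assert atp.stoichiometry == {"atp_c": -1, "h2o_c": -1,
                                 "adp_c": 1, "pi_c": 1, "h_c": 1}


def test_modelseed_resolution():
    mets = {f"{c}_c0": Metabolite(id=f"{c}_c0", compartment="c0")
            for c in ("cpd00002", "cpd00001", "cpd00008", "cpd00009",
                      "cpd00067", "cpd00027")}
    rxns = {"bio1": Reaction("bio1", {"cpd00027_c0": -1}, 0, 1000,
                             name="biomass")}
    model = MetabolicModel("seed", mets, rxns, "bio1", "modelseed")
    drs = {d.label: d for d in build_dissipation_reactions(model)}
    assert drs["ATP"].active
    assert drs["ATP"].stoichiometry == {
        "cpd00002_c0": -1, "cpd00001_c0": -1, "cpd00008_c0": 1,
        "cpd00009_c0": 1, "cpd00067_c0": 1}
    assert not drs["GTP"].active    # no GTP family metabolites


def test_missing_family_flagged_inactive():
    model, _ = make_fixture("fig6d")       # has no NAD pool
    drs = {d.label: d for d in build_dissipation_reactions(model)}
    assert drs["NADH"].integration < 1 and not drs["NADH"].active
    assert drs["NADH"].missing


def test_integration_is_exact_fraction():
    for name in ("fig6d", "fig6a", "viable_control"):
        model, _ = make_fixture(name)
        for d in build_dissipation_reactions(model):
            n = len(d.stoichiometry) + len(d.missing)
            k = len(d.stoichiometry)
            assert d.integration == k / n


def test_proton_gradient_compartment_handling():
    # cytosol-only energy pool: no periplasmic/external proton -> unresolvable
    model, _ = make_fixture("viable_control")
    drs = {d.label: d for d in build_dissipation_reactions(model)}
    assert not drs["HGRADIENT"].active
    # two-compartment model: falls back to the extracellular proton
    model, _ = make_fixture("fig2")
    drs = {d.label: d for d in build_dissipation_reactions(model)}
    assert drs["HGRADIENT"].active
    assert drs["HGRADIENT"].stoichiometry == {"h_e": -1, "h_c": 1}
    # three-compartment model: periplasmic proton preferred
    model, _ = make_fixture("fig6a")
    drs = {d.label: d for d in build_dissipation_reactions(model)}
    assert drs["HGRADIENT"].stoichiometry == {"h_p": -1, "h_c": 1}


def test_attached_edrs_are_irreversible():
    attached = egc.attach_default(make_fixture("fig6a")[0])
    edrs = [r for r in attached.reactions.values() if r.is_dissipation]
    assert edrs
    for r in edrs:
        assert r.lower_bound == 0.0 and r.upper_bound > 1.0


def test_attach_detach_round_trip():
    model, _ = make_fixture("fig6d")
    attached = egc.attach_default(model)
    back = detach_dissipation(attached)
    assert model_to_dict(back) == model_to_dict(model)


def test_attach_twice_is_an_error():
    attached = egc.attach_default(make_fixture("fig6d")[0])
    with pytest.raises(ValueError, match="already attached"):
        attach_dissipation(attached,
                           build_dissipation_reactions(attached))


def test_edr_id_collision_renamed():
    model, _ = make_fixture("viable_control")
    model.reactions["EDR_ATP"] = Reaction("EDR_ATP", {"atp_c": -1}, 0, 1,
                                          is_exchange=False)
    attached = attach_dissipation(model, build_dissipation_reactions(model))
    rid = attached.notes["edrs"]["ATP"]["reaction_id"]
    assert rid != "EDR_ATP" and rid in attached.reactions


def test_attachment_cannot_create_cycles():
    """Dissipation reactions strictly consume their energy metabolite, so an
    EGC-free model stays EGC-free after attachment."""
    model, _ = make_fixture("viable_control")
    report = egc.detect_egc(egc.attach_default(model))
    assert not report.has_egcs
    assert all(t.optimum <= 1e-9 for t in report.results.values())


def test_catalog_tsv_round_trip(tmp_path):
    cat = DissipationCatalog.default()
    path = tmp_path / "edr.tsv"
    cat.to_tsv(path)
    back = DissipationCatalog.from_tsv(path)
    assert set(back.entries) == set(cat.entries)
    for key in cat.entries:
        assert sorted(back.entries[key]) == sorted(cat.entries[key])
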