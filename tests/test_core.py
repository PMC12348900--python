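"""Network data model: GPR semantics, bound splitting, SBML round-trip,
medium and intervention application."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import gpr_truth_eval
from actd_cbm.core import (
    GprRule,
    Medium,
    MetabolicNetwork,
    Reaction,
    Species,
    TargetModification,
    TherapyCandidate,
    ValidationError,
    apply_candidate,
    apply_medium,
    eval_gpr,
    read_sbml,
    split_bounds,
    write_sbml,
)

# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "rule, knocked, active",
    [
        ("g1 or g2", {"g1"}, True),  # isozyme survives a single knockout
        ("g1 and g2", {"g1"}, False),  # complex dies with any subunit
        ("(g1 and g2) or g3", {"g1", "g3"}, False),
        ("(g1 and g2) or g3", {"g1"}, True),
        ("g1", set(), True),
        ("g1", {"g1"}, False),
    ],
)
def test_gpr_semantics(rule, knocked, active):
    parsed = GprRule.from_string(rule)
    assert eval_gpr(parsed, knocked) is active


def _gpr_strategy(genes):
    leaf = st.sampled_from(genes).map(lambda g: GprRule(op="gene", gene=g))
    return st.recursive(
        leaf,
        lambda children: st.tuples(
            st.sampled_from(["and", "or"]), st.lists(children, min_size=2, max_size=3)
        ).map(lambda t: GprRule(op=t[0], children=tuple(t[1]))),
        max_leaves=6,
    )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(rule=_gpr_strategy(["g1", "g2", "g3", "g4", "g5", "g6"]))
def test_gpr_matches_truth_table(rule):
    """Tree evaluation agrees with direct boolean evaluation of the rule
    text over every knockout pattern of the leaf genes."""
    genes = sorted(rule.genes)
    for mask in range(2 ** len(genes)):
        knocked = {g for i, g in enumerate(genes) if mask >> i & 1}
        expected = gpr_truth_eval(rule.to_string(), knocked, genes)
        assert rule.is_active(frozenset(knocked)) == expected


def test_gpr_roundtrip_string():
    text = "(g1 and g2) or (g3 and (g4 or g5))"
    rule = GprRule.from_string(text)
    again = GprRule.from_string(rule.to_string())
    assert rule == again


def test_eval_gpr_warns_on_unknown_knocked_gene():
    rule = GprRule.from_string("g1 or g2")
    with pytest.warns(UserWarning, match="not present"):
        assert eval_gpr(rule, {"gZ"}, known_genes={"g1", "g2"})


# ---------------------------------------------------------------------------
# Bounds and validation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "lb, ub, expected",
    [
        (-10.0, 10.0, (0.0, 10.0, 0.0, 10.0)),
        (0.0, 5.0, (0.0, 5.0, 0.0, 0.0)),
        (2.0, 10.0, (2.0, 10.0, 0.0, 0.0)),
        (-8.0, -2.0, (0.0, 0.0, 2.0, 8.0)),
    ],
)
def test_split_bounds_sign_convention(lb, ub, expected):
    assert split_bounds(lb, ub) == expected


def test_duplicate_species_rejected():
    sp = [Species(id="a_c", compartment="c"), Species(id="a_c", compartment="c")]
    with pytest.raises(ValidationError, match="duplicate species"):
        MetabolicNetwork(sp, [])


def test_reaction_bound_invariants():
    with pytest.raises(ValidationError, match="bounds"):
        Reaction(id="r", stoichiometry={"a": 1.0}, lb_f=5.0, ub_f=1.0)


# ---------------------------------------------------------------------------
# SBML round-trip
# ---------------------------------------------------------------------------


def test_sbml_roundtrip(toy_world, tmp_path):
    path = tmp_path / "net.xml"
    net = toy_world.disease
    write_sbml(net, str(path))
    back = read_sbml(str(path))
    assert back.species_ids == net.species_ids
    assert back.reaction_ids == net.reaction_ids
    for r1, r2 in zip(net.reactions, back.reactions):
        assert r1.stoichiometry == pytest.approx(r2.stoichiometry)
        assert r1.net_bounds == pytest.approx(r2.net_bounds)
        assert r1.is_exchange == r2.is_exchange
        if r1.gpr is not None:
            assert r2.gpr is not None and r1.gpr.to_string() == r2.gpr.to_string()
    # objective registry survives via reaction notes
    assert back.objectives.biomass == net.objectives.biomass
    assert back.objectives.atp == net.objectives.atp
    assert back.objectives.protein_synthesis == net.objectives.protein_synthesis
    assert back.objectives.protein_degradation == net.objectives.protein_degradation


def test_read_sbml_parse_failure(tmp_path):
    bad = tmp_path / "bad.xml"
    bad.write_text("<sbml>not really</sbml>")
    from actd_cbm.core import FormatError

    with pytest.raises(FormatError):
        read_sbml(str(bad))


# ---------------------------------------------------------------------------
# Medium application
# ---------------------------------------------------------------------------


def test_apply_medium_direct(toy_world):
    medium = Medium(name="m", uptake_bounds={"EX_glc__D_e": 7.5})
    net = apply_medium(toy_world.disease, medium)
    glc = net.get_reaction("EX_glc__D_e")
    assert glc.ub_b == 7.5
    # all other uptakes closed, secretion open
    for rxn in net.exchanges:
        if rxn.id != "EX_glc__D_e":
            assert rxn.ub_b == 0.0
        assert rxn.ub_f == 1000.0


def test_apply_medium_idempotent(toy_world):
    medium = toy_world.media[0]
    once = apply_medium(toy_world.healthy, medium)
    twice = apply_medium(once, medium)
    for r1, r2 in zip(once.reactions, twice.reactions):
        assert (r1.lb_f, r1.ub_f, r1.lb_b, r1.ub_b) == (r2.lb_f, r2.ub_f, r2.lb_b, r2.ub_b)


def test_empty_medium_starves(toy_world):
    from actd_cbm.pmofba import pmofba

    net = apply_medium(toy_world.disease, Medium(name="none", uptake_bounds={}))
    state = pmofba(net)
    # forced maintenance cannot be met without nutrients
    assert not state.feasible or state.zstar["BIOMASS"] < 1e-9


def test_apply_medium_rejects_non_exchange(toy_world):
    with pytest.raises(ValidationError, match="non-exchange"):
        apply_medium(toy_world.disease, Medium(name="m", uptake_bounds={"GLY1": 5.0}))


def test_two_media_differ_only_in_listed_bound(toy_world):
    m1 = Medium(name="a", uptake_bounds={"EX_glc__D_e": 10.0, "EX_nh4_e": 5.0})
    m2 = Medium(name="b", uptake_bounds={"EX_glc__D_e": 12.0, "EX_nh4_e": 5.0})
    n1 = apply_medium(toy_world.disease, m1)
    n2 = apply_medium(toy_world.disease, m2)
    diffs = [
        r1.id
        for r1, r2 in zip(n1.reactions, n2.reactions)
        if (r1.lb_f, r1.ub_f, r1.lb_b, r1.ub_b) != (r2.lb_f, r2.ub_f, r2.lb_b, r2.ub_b)
    ]
    assert diffs == ["EX_glc__D_e"]


# ---------------------------------------------------------------------------
# Candidate application
# ---------------------------------------------------------------------------


def _ko(*genes):
    return TargetModification("knockout", frozenset(genes))


def test_apply_empty_candidate_is_identity(toy_world):
    net = apply_candidate(toy_world.disease, TherapyCandidate())
    for r1, r2 in zip(toy_world.disease.reactions, net.reactions):
        assert (r1.lb_f, r1.ub_f, r1.lb_b, r1.ub_b) == (r2.lb_f, r2.ub_f, r2.lb_b, r2.ub_b)


def test_knockout_of_absent_gene_is_noop(toy_world):
    with pytest.warns(UserWarning, match="not present"):
        net = apply_candidate(toy_world.disease, TherapyCandidate((_ko("gNOPE"),)))
    for r1, r2 in zip(toy_world.disease.reactions, net.reactions):
        assert (r1.lb_f, r1.ub_f) == (r2.lb_f, r2.ub_f)


def test_knockout_zeroes_sole_gene_reaction(toy_world):
    net = apply_candidate(toy_world.disease, TherapyCandidate((_ko("gT"),)))
    glct = net.get_reaction("GLCt")
    assert (glct.lb_f, glct.ub_f, glct.lb_b, glct.ub_b) == (0, 0, 0, 0)
    # isozyme-backed branch survives a single-subunit knockout
    net2 = apply_candidate(toy_world.disease, TherapyCandidate((_ko("gA1"),)))
    assert net2.get_reaction("GLY1").ub_f > 0


def test_complex_knockout_requires_all_genes(toy_world):
    net = apply_candidate(toy_world.disease, TherapyCandidate((_ko("gR1"),)))
    assert net.get_reaction("RESP").ub_f == 0  # AND complex: one subunit enough
    net2 = apply_candidate(toy_world.disease, TherapyCandidate((_ko("gR1", "gR2"),)))
    assert net2.get_reaction("RESP").ub_f == 0


def test_upregulation_direct_rule():
    species = [Species(id="a_c", compartment="c")]
    reactions = [
        Reaction(id="EX_a", stoichiometry={"a_c": -1.0}, ub_b=10.0, is_exchange=True),
        Reaction(
            id="R",
            stoichiometry={"a_c": -1.0},
            ub_f=10.0,
            gpr=GprRule.from_string("g1"),
        ),
    ]
    net = MetabolicNetwork(species, reactions)
    up = TargetModification("upregulation", frozenset(["g1"]), magnitude=2.0)
    out = apply_candidate(net, TherapyCandidate((up,)), reference_flux={"R": 1.5})
    assert out.get_reaction("R").lb_f == pytest.approx(3.0)
    # capped at the upper bound
    out2 = apply_candidate(net, TherapyCandidate((up,)), reference_flux={"R": 8.0})
    assert out2.get_reaction("R").lb_f == pytest.approx(10.0)


def test_upregulation_zero_reference_warns():
    species = [Species(id="a_c", compartment="c")]
    reactions = [
        Reaction(id="EX_a", stoichiometry={"a_c": -1.0}, ub_b=10.0, is_exchange=True),
        Reaction(id="R", stoichiometry={"a_c": -1.0}, gpr=GprRule.from_string("g1")),
    ]
    net = MetabolicNetwork(species, reactions)
    up = TargetModification("upregulation", frozenset(["g1"]), magnitude=2.0)
    with pytest.warns(UserWarning, match="no-op"):
        apply_candidate(net, TherapyCandidate((up,)), reference_flux={"R": 0.0})


def test_candidate_gene_disjointness_enforced():
    with pytest.raises(ValidationError, match="two modifications"):
        TherapyCandidate((_ko("g1"), _ko("g1")))


def test_candidate_requires_reference_for_upregulation(toy_world):
    up = TargetModification("upregulation", frozenset(["gB"]), magnitude=2.0)
    with pytest.raises(ValidationError, match="reference"):
        apply_candidate(toy_world.disease, TherapyCandidate((up,)))
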