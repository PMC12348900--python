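"""Metabolite flow evaluation and variability envelopes."""

import numpy as np
import pytest

from actd_cbm.core import (
    MetabolicNetwork,
    Reaction,
    Species,
    ValidationError,
    apply_medium,
)
from actd_cbm.pmofba import FluxState, Objective, pmofba
from actd_cbm.pmfva import (
    FlowProfile,
    all_flows,
    consumption_flow,
    default_sigma_grid,
    flow_fva_mode,
    flow_variability,
    metabolite_flow,
    validate_sigma_grid,
)


def _state(net, vf, vb):
    return FluxState(
        reaction_ids=list(net.reaction_ids),
        vf=np.array(vf, dtype=float),
        vb=np.array(vb, dtype=float),
    )


@pytest.fixture()
def mini_net():
    species = [Species(id="m_c", compartment="c")]
    reactions = [
        Reaction(id="P", stoichiometry={"m_c": 1.0}, ub_f=10.0, ub_b=10.0),
        Reaction(id="C", stoichiometry={"m_c": -1.0}, ub_f=10.0, ub_b=10.0),
    ]
    return MetabolicNetwork(species, reactions)


def test_flow_direct_evaluation(mini_net):
    # producer (+1) forward at 2, consumer (-1) backward at 0.5 both produce
    state = _state(mini_net, vf=[2.0, 0.0], vb=[0.0, 0.5])
    assert metabolite_flow(state, mini_net, "m_c") == pytest.approx(2.5)


def test_flow_zero_for_untouched_metabolite(mini_net):
    state = _state(mini_net, vf=[0.0, 0.0], vb=[0.0, 0.0])
    assert metabolite_flow(state, mini_net, "m_c") == 0.0


def test_unknown_metabolite_rejected(mini_net):
    state = _state(mini_net, vf=[0.0, 0.0], vb=[0.0, 0.0])
    with pytest.raises(KeyError):
        metabolite_flow(state, mini_net, "nope_c")


def test_production_equals_consumption_on_feasible_states(toy_world):
    """Steady-state identity: the production-side sum equals the
    consumption-side sum for every species, on real solver output."""
    for sigma in (0.3, 1.0):
        net = apply_medium(toy_world.disease, toy_world.media[0])
        state = pmofba(net, weights=toy_world.disease_weights, sigma=sigma)
        assert state.feasible
        for sid in net.species_ids:
            prod = metabolite_flow(state, net, sid)
            cons = consumption_flow(state, net, sid)
            assert prod >= -1e-12
            assert prod == pytest.approx(cons, abs=1e-6)


def test_all_flows_vectorized_matches_scalar(toy_world):
    net = apply_medium(toy_world.healthy, toy_world.media[2])
    state = pmofba(net, weights=toy_world.healthy_weights)
    series = all_flows(state, net)
    for sid in ("atp_c", "pyr_c", "hmk_c"):
        assert series[sid] == pytest.approx(metabolite_flow(state, net, sid), abs=1e-9)


def test_sigma_grid_validation():
    validate_sigma_grid([0.0, 0.5, 1.0])
    with pytest.raises(ValidationError):
        validate_sigma_grid([0.0, 0.5])  # missing 1.0
    with pytest.raises(ValidationError):
        validate_sigma_grid([0.5, 0.5, 1.0])  # not strictly increasing
    with pytest.raises(ValidationError):
        validate_sigma_grid([1.0])


@pytest.fixture()
def forced_route_network():
    """EX -> S -> M -> drain; every unit of growth moves through M, so the
    flow of M equals the biomass flux exactly."""
    species = [Species(id="s_c", compartment="c"), Species(id="m_c", compartment="c")]
    reactions = [
        Reaction(id="EX_s", stoichiometry={"s_c": -1.0}, ub_b=10.0, is_exchange=True),
        Reaction(id="R1", stoichiometry={"s_c": -1.0, "m_c": 1.0}),
        Reaction(id="GROW", stoichiometry={"m_c": -1.0}),
    ]
    net = MetabolicNetwork(species, reactions)
    net.objectives.biomass = "GROW"
    return net


def test_sigma_sweep_matches_hand_lp(forced_route_network):
    """Hand solution: z1* = 10; at relaxation sigma the parsimonious state
    carries exactly sigma * 10 through M, so the envelope is [0, 10]."""
    profiles = flow_variability(
        forced_route_network,
        objectives=[Objective("GROW", "max", 1)],
        metabolites=["m_c"],
    )
    prof = profiles["m_c"]
    for sigma, flow in zip(prof.sigma, prof.flows):
        assert flow == pytest.approx(10.0 * sigma, abs=3e-5)
    assert prof.envelope == pytest.approx((0.0, 10.0), abs=3e-5)


def test_envelope_width_zero_when_route_forced(forced_route_network):
    """Forcing full growth at every sigma collapses the envelope."""
    net = forced_route_network.copy()
    net.get_reaction("GROW").lb_f = 10.0
    profiles = flow_variability(
        net, objectives=[Objective("GROW", "max", 1)], metabolites=["m_c"]
    )
    prof = profiles["m_c"]
    assert prof.r_max - prof.r_min == pytest.approx(0.0, abs=1e-6)


def test_envelope_containment_under_refinement(toy_world):
    net = apply_medium(toy_world.disease, toy_world.media[0])
    mets = ["atp_c", "pyr_c", "bmk_c"]
    coarse = flow_variability(
        net, weights=toy_world.disease_weights, metabolites=mets,
        grid=default_sigma_grid(11),
    )
    fine = flow_variability(
        net, weights=toy_world.disease_weights, metabolites=mets,
        grid=default_sigma_grid(101),
    )
    for sid in mets:
        assert fine[sid].r_min <= coarse[sid].r_min + 1e-9
        assert fine[sid].r_max >= coarse[sid].r_max - 1e-9


def test_flows_nonnegative_everywhere(toy_world):
    net = apply_medium(toy_world.healthy, toy_world.media[3])
    profiles = flow_variability(net, weights=toy_world.healthy_weights)
    for prof in profiles.values():
        assert np.all(prof.feasible_flows >= -1e-12)


def test_fva_mode_point_interval_on_forced_net(forced_route_network):
    net = forced_route_network.copy()
    net.get_reaction("GROW").lb_f = 10.0
    lo, hi = flow_fva_mode(
        net, None, [Objective("GROW", "max", 1)], "m_c", sigma=1.0
    )
    assert lo == pytest.approx(hi, abs=1e-6)
    assert lo == pytest.approx(10.0, abs=1e-6)


def test_fva_mode_without_cap_contains_sweep_value(two_path_network):
    objs = [Objective("DRAIN", "max", 1)]
    profiles = flow_variability(two_path_network, objectives=objs, metabolites=["b_c"])
    sweep_value = profiles["b_c"].flows[-1]  # sigma = 1
    lo, hi = flow_fva_mode(
        two_path_network, None, objs, "b_c", sigma=1.0, eps=np.inf
    )
    assert lo - 1e-4 <= sweep_value <= hi + 1e-4


def test_fva_mode_two_path_hand_interval(two_path_network):
    """At sigma = 1 the drain must carry 10, so the flow of the junction
    metabolite is pinned to 10 however the routes split; with the
    parsimony cap the interval collapses to the cheap route's flow."""
    objs = [Objective("DRAIN", "max", 1)]
    lo, hi = flow_fva_mode(two_path_network, None, objs, "b_c", sigma=1.0, eps=1e-4)
    assert lo == pytest.approx(10.0, abs=1e-3)
    assert hi == pytest.approx(10.0, abs=1e-3)
    # the intermediate x is free without a cap: 0 (shortcut) .. 10 (long way)
    lo_x, hi_x = flow_fva_mode(two_path_network, None, objs, "x_c", sigma=1.0, eps=np.inf)
    assert lo_x == pytest.approx(0.0, abs=1e-6)
    assert hi_x == pytest.approx(10.0, abs=1e-6)


def test_all_grid_points_infeasible_raises(chain_network):
    net = chain_network.copy()
    net.get_reaction("GROW").lb_f = 50.0
    with pytest.raises(ValidationError, match="infeasible"):
        flow_variability(net, objectives=[Objective("GROW", "max", 1)])
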