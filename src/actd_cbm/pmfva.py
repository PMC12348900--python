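"""Parsimonious metabolite flow variability analysis.

The *flow* of a metabolite m in a split-flux state is its total production
rate,

    r_m = sum_{N_mj > 0} N_mj vf_j  +  sum_{N_mj < 0} (-N_mj) vb_j ,

a nonnegative quantity that equals the total consumption rate at steady
state.  Sweeping the relaxation parameter sigma of the parsimonious
two-stage problem over a grid in [0, 1] yields a flow profile per
metabolite whose envelope [r_min, r_max] summarizes how much the flow can
vary between fully optimal (sigma = 1) and unconstrained-by-objectives
(sigma = 0) metabolic states.

``flow_variability`` implements this sigma sweep (the primary mode).
``flow_fva_mode`` is the literal bilevel alternative: at a fixed sigma it
maximizes / minimizes one metabolite's flow subject to the stage
constraints plus a parsimony cap on the weighted total flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from actd_cbm.core import MetabolicNetwork, ValidationError
from actd_cbm.pmofba import (
    FluxState,
    Objective,
    _SplitLP,
    _weight_array,
    default_objectives,
    solve_mofba,
    solve_ufd,
)


def default_sigma_grid(n_points: int = 11) -> np.ndarray:
    return np.linspace(0.0, 1.0, n_points)


def validate_sigma_grid(grid: Sequence[float]) -> np.ndarray:
    arr = np.asarray(grid, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValidationError("sigma grid needs at least two values")
    if np.any(np.diff(arr) <= 0):
        raise ValidationError("sigma grid must be strictly increasing")
    if arr[0] < 0 or arr[-1] > 1:
        raise ValidationError("sigma grid must lie in [0, 1]")
    if not np.isclose(arr[-1], 1.0):
        raise ValidationError("sigma grid must contain 1.0")
    return arr


@dataclass
class FlowProfile:
    """Per-sigma flow of one metabolite plus its variability envelope."""

    metabolite_id: str
    sigma: np.ndarray
    flows: np.ndarray  # NaN at infeasible grid points
    feasible: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.feasible is None:
            self.feasible = ~np.isnan(self.flows)
        if self.sigma.shape != self.flows.shape:
            raise ValidationError("sigma and flow arrays must align")

    @property
    def feasible_flows(self) -> np.ndarray:
        return self.flows[self.feasible]

    @property
    def r_min(self) -> float:
        vals = self.feasible_flows
        return float(np.min(vals)) if vals.size else float("nan")

    @property
    def r_max(self) -> float:
        vals = self.feasible_flows
        return float(np.max(vals)) if vals.size else float("nan")

    @property
    def envelope(self) -> tuple[float, float]:
        return (self.r_min, self.r_max)


def _production_coeffs(network: MetabolicNetwork, metabolite: str) -> np.ndarray:
    """Coefficients c such that r_m = c @ [vf; vb] (all entries >= 0)."""
    if metabolite not in set(network.species_ids):
        raise KeyError(f"metabolite {metabolite!r} not in network")
    n = len(network.reactions)
    c = np.zeros(2 * n)
    for j, rxn in enumerate(network.reactions):
        coeff = rxn.stoichiometry.get(metabolite, 0.0)
        if coeff > 0:
            c[j] = coeff  # produced by forward flux
        elif coeff < 0:
            c[n + j] = -coeff  # produced by backward flux
    return c


def metabolite_flow(state: FluxState, network: MetabolicNetwork, metabolite: str) -> float:
    """Total production rate of one metabolite in a flux state."""
    if not state.feasible:
        raise ValidationError("cannot evaluate flows of an infeasible state")
    c = _production_coeffs(network, metabolite)
    x = np.concatenate([state.vf, state.vb])
    return float(c @ x)


def all_flows(state: FluxState, network: MetabolicNetwork) -> pd.Series:
    """Flows of every species, as a pandas Series indexed by species id."""
    if not state.feasible:
        raise ValidationError("cannot evaluate flows of an infeasible state")
    N = network.stoichiometric_matrix()
    pos = N.maximum(0)
    neg = (-N).maximum(0)
    flows = pos @ state.vf + neg @ state.vb
    return pd.Series(np.asarray(flows).ravel(), index=network.species_ids)


def consumption_flow(state: FluxState, network: MetabolicNetwork, metabolite: str) -> float:
    """Total consumption rate (the steady-state mirror of the flow)."""
    if metabolite not in set(network.species_ids):
        raise KeyError(f"metabolite {metabolite!r} not in network")
    n = len(network.reactions)
    c = np.zeros(2 * n)
    for j, rxn in enumerate(network.reactions):
        coeff = rxn.stoichiometry.get(metabolite, 0.0)
        if coeff < 0:
            c[j] = -coeff  # consumed by forward flux
        elif coeff > 0:
            c[n + j] = coeff  # consumed by backward flux
    return float(c @ np.concatenate([state.vf, state.vb]))


def flow_variability(
    network: MetabolicNetwork,
    weights: Optional[Mapping[str, float]] = None,
    objectives: Optional[Sequence[Objective]] = None,
    metabolites: Optional[Sequence[str]] = None,
    grid: Optional[Sequence[float]] = None,
    paper_literal: bool = False,
) -> dict[str, FlowProfile]:
    """Sigma-sweep flow profiles and envelopes for the given metabolites
    (default: all species).  Infeasible grid points are recorded as NaN
    and excluded from the envelope; an error is raised only when every
    grid point is infeasible."""
    sigmas = validate_sigma_grid(grid if grid is not None else default_sigma_grid())
    objectives = list(objectives) if objectives is not None else default_objectives(network)
    mets = list(metabolites) if metabolites is not None else list(network.species_ids)
    known = set(network.species_ids)
    unknown = [m for m in mets if m not in known]
    if unknown:
        raise KeyError(f"metabolite(s) not in network: {unknown}")

    zstar, status = solve_mofba(network, objectives)
    flows = np.full((len(mets), sigmas.size), np.nan)
    if status == "optimal":
        for k, sigma in enumerate(sigmas):
            state = solve_ufd(
                network, weights, zstar, sigma=float(sigma), objectives=objectives,
                paper_literal=paper_literal,
            )
            if not state.feasible:
                continue
            series = all_flows(state, network)
            flows[:, k] = series.loc[mets].to_numpy()
    if np.all(np.isnan(flows)):
        raise ValidationError(
            "flow variability: every sigma grid point is infeasible"
        )
    return {
        m: FlowProfile(metabolite_id=m, sigma=sigmas.copy(), flows=flows[i])
        for i, m in enumerate(mets)
    }


def flow_fva_mode(
    network: MetabolicNetwork,
    weights: Optional[Mapping[str, float]],
    objectives: Optional[Sequence[Objective]],
    metabolite: str,
    sigma: float,
    eps: float = 1e-4,
    paper_literal: bool = False,
) -> tuple[float, float]:
    """Min/max flow of one metabolite at fixed sigma, subject to the stage
    constraints plus the parsimony cap
    ``sum w (vf + vb) <= (1 + eps) * UFD optimum``.  ``eps=np.inf`` drops
    the cap."""
    objectives = list(objectives) if objectives is not None else default_objectives(network)
    base = solve_ufd_state = None
    zstar, status = solve_mofba(network, objectives)
    if status != "optimal":
        raise ValidationError(f"stage-1 problem {status}")
    base = solve_ufd(
        network, weights, zstar, sigma=sigma, objectives=objectives,
        paper_literal=paper_literal,
    )
    if not base.feasible:
        raise ValidationError(f"UFD problem infeasible at sigma={sigma}")

    w = _weight_array(network, weights)
    lp = _SplitLP(network)
    top_rank = min(o.rank for o in objectives)
    for obj in sorted(objectives, key=lambda o: o.rank):
        level = sigma * zstar[obj.reaction_id]
        row = lp.net_row(obj.reaction_id)
        direction = (
            ("ge" if obj.rank == top_rank else "le") if paper_literal else obj.relax_direction
        )
        if direction == "ge":
            lp.add_le(-row, -level)
        else:
            lp.add_le(row, level)
    if np.isfinite(eps):
        cap = (1.0 + eps) * base.total_weighted_flux + 1e-9
        lp.add_le(np.concatenate([w, w]), cap)

    c = _production_coeffs(network, metabolite)
    x_min, st_min = lp.solve(c)
    x_max, st_max = lp.solve(-c)
    if x_min is None or x_max is None:
        raise ValidationError(
            f"flow FVA infeasible for {metabolite!r} at sigma={sigma}"
        )
    return (float(c @ x_min), float(c @ x_max))


def profiles_to_frame(profiles: Mapping[str, FlowProfile]) -> pd.DataFrame:
    """Long-format table (metabolite_id, sigma, flow)."""
    rows = []
    for mid in sorted(profiles):
        prof = profiles[mid]
        for s, f in zip(prof.sigma, prof.flows):
            rows.append((mid, float(s), float(f)))
    return pd.DataFrame(rows, columns=["metabolite_id", "sigma", "flow"])


def envelopes_to_frame(profiles: Mapping[str, FlowProfile]) -> pd.DataFrame:
    rows = [
        (mid, profiles[mid].r_min, profiles[mid].r_max) for mid in sorted(profiles)
    ]
    return pd.DataFrame(rows, columns=["metabolite_id", "r_min", "r_max"])
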