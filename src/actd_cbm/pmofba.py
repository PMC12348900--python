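"""Two-stage parsimonious multi-objective flux balance analysis.

Stage 1 (MOFBA) maximizes the named cellular objectives — biomass, ATP
hydrolysis, per-protein synthesis or degradation — lexicographically in
priority order over the split-flux polytope

    N (vf - vb) = 0,   0 <= vf <= ub_f,   0 <= vb <= ub_b,

fixing each optimum (within a relative tolerance) before moving to the
next rank.  Stage 2 (UFD, uniform flux distribution) minimizes the total
transcriptome-weighted flux  sum_i w_i (vf_i + vb_i)  subject to the same
polytope plus relaxed objective constraints at level ``sigma * z*``
(sigma in [0, 1]; sigma = 1 demands full objective performance).

By default every maximized objective is relaxed downward (z >= sigma z*).
The alternative dialect ``paper_literal=True`` keeps z1 >= sigma z1* for
the top-priority objective but constrains all lower-priority maximized
objectives from above (z <= sigma z*).

All LPs are solved deterministically with scipy's HiGHS backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from actd_cbm.core import MetabolicNetwork, ValidationError

FIX_TOL = 1e-6  # relative tolerance when freezing lexicographic levels


@dataclass(frozen=True)
class Objective:
    """One ranked cellular objective."""

    reaction_id: str
    sense: str = "max"  # "max" | "min"
    rank: int = 1
    relax: Optional[str] = None  # "ge" | "le"; default: ge for max, le for min

    def __post_init__(self) -> None:
        if self.sense not in ("max", "min"):
            raise ValidationError(f"objective sense must be max/min, got {self.sense!r}")
        if self.relax not in (None, "ge", "le"):
            raise ValidationError(f"objective relax must be ge/le, got {self.relax!r}")

    @property
    def relax_direction(self) -> str:
        if self.relax is not None:
            return self.relax
        return "ge" if self.sense == "max" else "le"


def validate_objectives(network: MetabolicNetwork, objectives: Sequence[Objective]) -> None:
    rids = set(network.reaction_ids)
    ranks = [o.rank for o in objectives]
    if len(set(ranks)) != len(ranks):
        raise ValidationError("objective priority ranks must be unique")
    for obj in objectives:
        if obj.reaction_id not in rids:
            raise ValidationError(f"objective reaction {obj.reaction_id!r} not in network")


def default_objectives(
    network: MetabolicNetwork, protein_sense: str = "synthesis"
) -> list[Objective]:
    """Objectives from the network's registry: biomass (rank 1), ATP
    hydrolysis (rank 2), then per-protein synthesis or degradation."""
    objs: list[Objective] = []
    rank = 1
    if network.objectives.biomass:
        objs.append(Objective(network.objectives.biomass, "max", rank))
        rank += 1
    if network.objectives.atp:
        objs.append(Objective(network.objectives.atp, "max", rank))
        rank += 1
    registry = (
        network.objectives.protein_synthesis
        if protein_sense == "synthesis"
        else network.objectives.protein_degradation
    )
    for name in sorted(registry):
        objs.append(Objective(registry[name], "max", rank))
        rank += 1
    if not objs:
        raise ValidationError("network has no registered objective reactions")
    return objs


@dataclass
class FluxState:
    """Solution of a (p)MOFBA problem in the split-flux representation."""

    reaction_ids: list[str]
    vf: np.ndarray
    vb: np.ndarray
    objective_values: dict[str, float] = field(default_factory=dict)
    zstar: dict[str, float] = field(default_factory=dict)
    total_weighted_flux: float = float("nan")
    status: str = "optimal"
    sigma: Optional[float] = None

    @property
    def feasible(self) -> bool:
        return self.status == "optimal"

    @property
    def net(self) -> np.ndarray:
        return self.vf - self.vb

    def net_flux(self, reaction_id: str) -> float:
        return float(self.net[self.reaction_ids.index(reaction_id)])

    def net_map(self) -> dict[str, float]:
        net = self.net
        return {rid: float(net[i]) for i, rid in enumerate(self.reaction_ids)}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "reaction_id": self.reaction_ids,
                "vf": self.vf,
                "vb": self.vb,
                "net": self.net,
            }
        )

    @classmethod
    def infeasible(
        cls, network: MetabolicNetwork, sigma: Optional[float] = None, status: str = "infeasible"
    ) -> "FluxState":
        n = len(network.reactions)
        return cls(
            reaction_ids=list(network.reaction_ids),
            vf=np.full(n, np.nan),
            vb=np.full(n, np.nan),
            status=status,
            sigma=sigma,
        )


class _SplitLP:
    """Shared LP skeleton over x = [vf; vb]."""

    def __init__(self, network: MetabolicNetwork) -> None:
        self.network = network
        self.n = len(network.reactions)
        N = network.stoichiometric_matrix()
        self.A_eq = sparse.hstack([N, -N], format="csr")
        self.b_eq = np.zeros(N.shape[0])
        self.bounds = [(r.lb_f, r.ub_f) for r in network.reactions] + [
            (r.lb_b, r.ub_b) for r in network.reactions
        ]
        self.rindex = network.reaction_index()
        # accumulated inequality rows A_ub x <= b_ub
        self._ub_rows: list[np.ndarray] = []
        self._ub_vals: list[float] = []

    def net_row(self, reaction_id: str) -> np.ndarray:
        row = np.zeros(2 * self.n)
        j = self.rindex[reaction_id]
        row[j] = 1.0
        row[self.n + j] = -1.0
        return row

    def add_le(self, row: np.ndarray, value: float) -> None:
        self._ub_rows.append(row)
        self._ub_vals.append(value)

    def solve(self, c: np.ndarray) -> tuple[Optional[np.ndarray], str]:
        A_ub = np.vstack(self._ub_rows) if self._ub_rows else None
        b_ub = np.array(self._ub_vals) if self._ub_rows else None
        res = linprog(
            c,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=self.A_eq,
            b_eq=self.b_eq,
            bounds=self.bounds,
            method="highs",
        )
        if not res.success:
            status = "infeasible" if res.status == 2 else f"solver_status_{res.status}"
            return None, status
        return res.x, "optimal"


def _slack(level: float, tol: float = FIX_TOL) -> float:
    # relative slack with a tiny absolute floor; keeps sigma = 1 within
    # 1e-6 relative of the stage-1 optima while absorbing solver rounding
    return tol * abs(level) + 1e-9


def _fix_level(lp: _SplitLP, obj: Objective, level: float, tol: float = FIX_TOL) -> None:
    slack = _slack(level, tol)
    row = lp.net_row(obj.reaction_id)
    if obj.sense == "max":
        lp.add_le(-row, -(level - slack))
    else:
        lp.add_le(row, level + slack)


def solve_mofba(
    network: MetabolicNetwork,
    objectives: Optional[Sequence[Objective]] = None,
    tol: float = FIX_TOL,
) -> tuple[dict[str, float], str]:
    """Lexicographic stage-1 solve; returns ({reaction_id: z*}, status).

    On infeasibility the z* map is empty and the status is "infeasible";
    callers decide how to score such models.
    """
    objectives = list(objectives) if objectives is not None else default_objectives(network)
    validate_objectives(network, objectives)
    lp = _SplitLP(network)
    zstar: dict[str, float] = {}
    for obj in sorted(objectives, key=lambda o: o.rank):
        row = lp.net_row(obj.reaction_id)
        c = -row if obj.sense == "max" else row
        x, status = lp.solve(c)
        if x is None:
            return {}, status
        level = float(row @ x)
        zstar[obj.reaction_id] = level
        _fix_level(lp, obj, level, tol)
    return zstar, "optimal"


def solve_ufd(
    network: MetabolicNetwork,
    weights: Optional[Mapping[str, float] | np.ndarray],
    zstar: Mapping[str, float],
    sigma: float = 1.0,
    objectives: Optional[Sequence[Objective]] = None,
    paper_literal: bool = False,
) -> FluxState:
    """Stage-2 weighted total-flux minimization at relaxation level sigma."""
    if not (0.0 <= sigma <= 1.0):
        raise ValidationError(f"sigma must lie in [0, 1], got {sigma}")
    objectives = list(objectives) if objectives is not None else default_objectives(network)
    validate_objectives(network, objectives)
    w = _weight_array(network, weights)
    lp = _SplitLP(network)
    top_rank = min(o.rank for o in objectives)
    for obj in sorted(objectives, key=lambda o: o.rank):
        if obj.reaction_id not in zstar:
            raise ValidationError(
                f"no stage-1 level for objective reaction {obj.reaction_id!r}"
            )
        level = sigma * zstar[obj.reaction_id]
        # same relative slack used when freezing the lexicographic levels;
        # without it sigma = 1 would demand the stage-1 optima exactly and
        # fail on rounding noise
        slack = _slack(level)
        row = lp.net_row(obj.reaction_id)
        if paper_literal:
            direction = "ge" if obj.rank == top_rank else "le"
        else:
            direction = obj.relax_direction
        if direction == "ge":
            lp.add_le(-row, -(level - slack))
        else:
            lp.add_le(row, level + slack)
    c = np.concatenate([w, w])
    x, status = lp.solve(c)
    if x is None:
        return FluxState.infeasible(network, sigma=sigma, status=status)
    n = lp.n
    state = FluxState(
        reaction_ids=list(network.reaction_ids),
        vf=x[:n],
        vb=x[n:],
        zstar=dict(zstar),
        total_weighted_flux=float(c @ x),
        sigma=sigma,
    )
    net = state.net
    ridx = network.reaction_index()
    state.objective_values = {
        o.reaction_id: float(net[ridx[o.reaction_id]]) for o in objectives
    }
    return state


def pmofba(
    network: MetabolicNetwork,
    weights: Optional[Mapping[str, float] | np.ndarray] = None,
    objectives: Optional[Sequence[Objective]] = None,
    sigma: float = 1.0,
    paper_literal: bool = False,
) -> FluxState:
    """Composition of the two stages: MOFBA levels, then the parsimonious
    UFD state at relaxation ``sigma``."""
    objectives = list(objectives) if objectives is not None else default_objectives(network)
    zstar, status = solve_mofba(network, objectives)
    if status != "optimal":
        return FluxState.infeasible(network, sigma=sigma, status=status)
    return solve_ufd(
        network, weights, zstar, sigma=sigma, objectives=objectives,
        paper_literal=paper_literal,
    )


def _weight_array(
    network: MetabolicNetwork, weights: Optional[Mapping[str, float] | np.ndarray]
) -> np.ndarray:
    n = len(network.reactions)
    if weights is None:
        return np.ones(n)
    if hasattr(weights, "weights") and not isinstance(weights, (Mapping, np.ndarray)):
        weights = weights.weights  # ConfidenceAssignment

    if isinstance(weights, np.ndarray):
        if weights.shape != (n,):
            raise ValidationError(
                f"weight vector has shape {weights.shape}, expected ({n},)"
            )
        return weights.astype(float)
    return np.array([float(weights.get(r.id, 1.0)) for r in network.reactions])
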