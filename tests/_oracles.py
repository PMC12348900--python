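"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: LP optima are obtained
by exhaustive enumeration of basic feasible solutions (polytope vertices),
GPR semantics by evaluating the boolean formula text, and small networks
are generated directly as random chains.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

from actd_cbm.core import MetabolicNetwork, Reaction, Species
from actd_cbm.pmofba import _slack

_SLACK_UB = 1e7  # upper bound for slack variables of <= rows


def enumerate_vertices(
    A_eq: np.ndarray,
    b_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
    tol: float = 1e-9,
) -> np.ndarray:
    """All basic feasible solutions of {A_eq x = b_eq, A_ub x <= b_ub,
    lb <= x <= ub}, returned as rows (original variables only).

    Inequality rows are converted to equalities with bounded slacks.  For
    every basis (column subset of size rank) the remaining variables are
    pinned to each combination of their bounds and the square system is
    solved for all combinations at once.
    """
    A = np.asarray(A_eq, dtype=float)
    b = np.asarray(b_eq, dtype=float)
    lo = np.asarray(lb, dtype=float)
    hi = np.asarray(ub, dtype=float)
    n_orig = A.shape[1]
    if A_ub is not None and len(A_ub):
        A_ub = np.asarray(A_ub, dtype=float)
        b_ub = np.asarray(b_ub, dtype=float)
        k = A_ub.shape[0]
        A = np.block([[A, np.zeros((A.shape[0], k))], [A_ub, np.eye(k)]])
        b = np.concatenate([b, b_ub])
        lo = np.concatenate([lo, np.zeros(k)])
        hi = np.concatenate([hi, np.full(k, _SLACK_UB)])
    m, d = A.shape
    r = np.linalg.matrix_rank(A)
    if r < m:
        # drop dependent rows (QR pivoting via row echelon on random combo)
        keep: list[int] = []
        for i in range(m):
            trial = keep + [i]
            if np.linalg.matrix_rank(A[trial]) == len(trial):
                keep.append(i)
        A, b = A[keep], b[keep]
        m = len(keep)

    vertices = []
    n_free = d - m
    bound_combos = np.array(list(product([0, 1], repeat=n_free)), dtype=float)
    for basis in combinations(range(d), m):
        basis = list(basis)
        nonbasis = [j for j in range(d) if j not in basis]
        A_B = A[:, basis]
        det_ok = np.abs(np.linalg.det(A_B)) > 1e-12 if m else True
        if not det_ok:
            continue
        # columns: each bound combo for the nonbasic variables
        x_N = lo[nonbasis][None, :] * (1 - bound_combos) + hi[nonbasis][None, :] * bound_combos
        rhs = b[:, None] - A[:, nonbasis] @ x_N.T
        try:
            x_B = np.linalg.solve(A_B, rhs)
        except np.linalg.LinAlgError:
            continue
        ok = np.all(
            (x_B >= lo[basis][:, None] - tol) & (x_B <= hi[basis][:, None] + tol),
            axis=0,
        )
        for col in np.nonzero(ok)[0]:
            x = np.empty(d)
            x[basis] = x_B[:, col]
            x[nonbasis] = x_N[col]
            vertices.append(x[:n_orig])
    if not vertices:
        return np.empty((0, n_orig))
    return np.unique(np.round(np.array(vertices), 9), axis=0)


def _split_system(network: MetabolicNetwork):
    N = network.stoichiometric_matrix().toarray()
    A_eq = np.hstack([N, -N])
    b_eq = np.zeros(N.shape[0])
    lb = np.array([r.lb_f for r in network.reactions] + [r.lb_b for r in network.reactions])
    ub = np.array([r.ub_f for r in network.reactions] + [r.ub_b for r in network.reactions])
    return A_eq, b_eq, lb, ub


def _net_row(network: MetabolicNetwork, rid: str) -> np.ndarray:
    n = len(network.reactions)
    row = np.zeros(2 * n)
    j = network.reaction_index()[rid]
    row[j], row[n + j] = 1.0, -1.0
    return row


def oracle_lexicographic(network: MetabolicNetwork, objective_ids: list[str], tol: float = 1e-7):
    """Lexicographic maxima via vertex enumeration, mirroring the
    slack-relaxed level-fixing of the two-stage method."""
    A_eq, b_eq, lb, ub = _split_system(network)
    A_ub_rows: list[np.ndarray] = []
    b_ub_vals: list[float] = []
    zstar = {}
    for rid in objective_ids:
        row = _net_row(network, rid)
        verts = enumerate_vertices(
            A_eq, b_eq, lb, ub,
            A_ub=np.array(A_ub_rows) if A_ub_rows else None,
            b_ub=np.array(b_ub_vals) if b_ub_vals else None,
        )
        if verts.shape[0] == 0:
            return None
        values = verts @ row
        level = float(values.max())
        zstar[rid] = level
        A_ub_rows.append(-row)
        b_ub_vals.append(-(level - _slack(level)))
    return zstar


def oracle_ufd_minimum(
    network: MetabolicNetwork,
    weights: np.ndarray,
    zstar: dict[str, float],
    sigma: float,
) -> float:
    """Minimal weighted total flux at relaxation sigma, via vertex
    enumeration of the constrained polytope."""
    A_eq, b_eq, lb, ub = _split_system(network)
    A_ub_rows, b_ub_vals = [], []
    for rid, z in zstar.items():
        level = sigma * z
        row = _net_row(network, rid)
        A_ub_rows.append(-row)
        b_ub_vals.append(-(level - _slack(level)))
    verts = enumerate_vertices(
        A_eq, b_eq, lb, ub, A_ub=np.array(A_ub_rows), b_ub=np.array(b_ub_vals)
    )
    if verts.shape[0] == 0:
        return float("nan")
    c = np.concatenate([weights, weights])
    return float((verts @ c).min())


def random_chain_network(rng: np.random.Generator) -> tuple[MetabolicNetwork, list[str]]:
    """A random feasible chain network with <= 6 reactions: one uptake, a
    couple of conversions (random yields), and two objective drains."""
    m = int(rng.integers(2, 4))  # internal species
    species = [Species(id=f"s{i}", compartment="c") for i in range(m)]
    reactions = [
        Reaction(
            id="UPT",
            stoichiometry={"s0": 1.0},
            ub_f=float(rng.uniform(2.0, 10.0)),
            is_exchange=True,
        )
    ]
    for i in range(m - 1):
        coeff = float(rng.uniform(0.5, 2.0))
        reversible = bool(rng.random() < 0.3)
        reactions.append(
            Reaction(
                id=f"C{i}",
                stoichiometry={f"s{i}": -1.0, f"s{i+1}": coeff},
                ub_f=float(rng.uniform(5.0, 20.0)),
                ub_b=float(rng.uniform(1.0, 5.0)) if reversible else 0.0,
            )
        )
    # two drains from the last species (competing objectives) and maybe a
    # side drain from s0
    last = f"s{m-1}"
    reactions.append(
        Reaction(id="OBJ1", stoichiometry={last: -1.0}, ub_f=float(rng.uniform(3.0, 15.0)))
    )
    reactions.append(
        Reaction(
            id="OBJ2",
            stoichiometry={last: -1.0, "s0": float(rng.uniform(0.0, 0.4))},
            ub_f=float(rng.uniform(3.0, 15.0)),
        )
    )
    if rng.random() < 0.5 and len(reactions) < 6:
        reactions.append(
            Reaction(id="SIDE", stoichiometry={"s0": -1.0}, ub_f=float(rng.uniform(0.5, 3.0)))
        )
    net = MetabolicNetwork(species=species, reactions=reactions, id="chain")
    return net, ["OBJ1", "OBJ2"]


def gpr_truth_eval(rule_text: str, knocked: set[str], genes: list[str]) -> bool:
    """Evaluate a GPR formula string directly with Python booleans."""
    env = {g: g not in knocked for g in genes}
    return bool(eval(rule_text, {"__builtins__": {}}, env))  # noqa: S307
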