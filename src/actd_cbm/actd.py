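"""Fuzzy multi-objective anticancer target discovery.

Each therapy candidate (knockouts / upregulations of genes or enzyme
complexes, singly or in pairs) is scored per nutritional medium by two
fuzzy grades:

* **cell viability** ``eta_CV``: how completely the treatment suppresses
  the diseased cell's objectives (biomass first, then ATP and protein
  turnover).  Each minimized quantity is graded by a decreasing linear
  membership function; the grades are aggregated by minimum, so the
  candidate is only as good as its worst-suppressed objective.  An
  infeasible treated disease model counts as a full kill (grade 1).

* **metabolic deviation** ``eta_MD``: how safe the treatment is for the
  healthy cell.  The perturbed-healthy flux state is compared with the
  unperturbed healthy template (fuzzy similarity, two-sided membership
  centered on the template flux) and with the diseased template (fuzzy
  dissimilarity); the two mean grades are averaged 50/50.  An infeasible
  perturbed healthy model counts as maximal side effect (grade 0).

The grades are combined into a fuzzy decision score ``eta_D`` (max-min
decision: minimum over all grades, media and disease models), and the
candidate space is searched with a nested hybrid differential evolution:
an outer DE population over integer-encoded candidates (continuous
relaxation + rounding, binomial crossover, greedy selection) with a
migration/restart operator on diversity collapse; every fitness
evaluation solves the inner parsimonious multi-objective LPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np

from actd_cbm.core import (
    Medium,
    MetabolicNetwork,
    TargetModification,
    TherapyCandidate,
    ValidationError,
    apply_candidate,
    apply_medium,
)
from actd_cbm.pmofba import FluxState, Objective, default_objectives, pmofba

# ---------------------------------------------------------------------------
# Membership functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MembershipFunction:
    """Piecewise-linear fuzzy membership on an objective's scale."""

    shape: str  # one_sided_increasing | one_sided_decreasing | two_sided
    lb: float
    ub: float
    st: Optional[float] = None  # two_sided only

    def __post_init__(self) -> None:
        if self.shape not in (
            "one_sided_increasing",
            "one_sided_decreasing",
            "two_sided",
        ):
            raise ValidationError(f"unknown membership shape {self.shape!r}")
        if not self.lb < self.ub:
            raise ValidationError("membership requires LB < UB")
        if self.shape == "two_sided":
            if self.st is None or not (self.lb < self.st < self.ub):
                raise ValidationError("two-sided membership requires LB < ST < UB")

    def grade(self, value: float) -> float:
        if self.shape == "one_sided_increasing":
            if value <= self.lb:
                return 0.0
            if value >= self.ub:
                return 1.0
            return (value - self.lb) / (self.ub - self.lb)
        if self.shape == "one_sided_decreasing":
            if value <= self.lb:
                return 1.0
            if value >= self.ub:
                return 0.0
            return (self.ub - value) / (self.ub - self.lb)
        # two_sided
        if value <= self.lb or value >= self.ub:
            return 0.0
        if value == self.st:
            return 1.0
        if value < self.st:
            return (value - self.lb) / (self.st - self.lb)
        return (self.ub - value) / (self.ub - self.st)


def membership_grade(value: float, fn: MembershipFunction) -> float:
    return fn.grade(value)


def two_sided_band(center: float, rel_band: float, abs_floor: float) -> MembershipFunction:
    """Two-sided membership centered on a template flux with half-width
    ``max(rel_band * |center|, abs_floor)``."""
    half = max(rel_band * abs(center), abs_floor)
    return MembershipFunction("two_sided", lb=center - half, ub=center + half, st=center)


# ---------------------------------------------------------------------------
# Grades
# ---------------------------------------------------------------------------

_ZERO_OBJECTIVE_TOL = 1e-9


def default_cv_membership(zstar: Mapping[str, float]) -> dict[str, MembershipFunction]:
    """Decreasing membership per objective: LB = 0, UB = the untreated
    optimum (full suppression -> grade 1, untreated level -> grade 0).
    Objectives already at zero in the untreated cell are graded by a
    narrow band so that keeping them at zero scores 1."""
    fns = {}
    for rid, z in zstar.items():
        ub = abs(z)
        if ub <= _ZERO_OBJECTIVE_TOL:
            ub = _ZERO_OBJECTIVE_TOL
        fns[rid] = MembershipFunction("one_sided_decreasing", lb=0.0, ub=ub)
    return fns


def cell_viability(
    treated_state: FluxState,
    objectives: Sequence[Objective],
    fns: Mapping[str, MembershipFunction],
    aggregation: str = "min",
) -> tuple[float, dict[str, float]]:
    """Fuzzy cell-viability grade of a treated disease model.

    Returns (eta_CV, per-objective grades).  Infeasible treated model ->
    eta_CV = 1 (maximal kill)."""
    if not treated_state.feasible:
        return 1.0, {}
    grades: dict[str, float] = {}
    for obj in objectives:
        fn = fns.get(obj.reaction_id)
        if fn is None:
            raise ValidationError(
                f"no membership function for objective {obj.reaction_id!r}"
            )
        grades[obj.reaction_id] = fn.grade(
            treated_state.objective_values[obj.reaction_id]
        )
    vals = list(grades.values())
    eta = min(vals) if aggregation == "min" else float(np.mean(vals))
    return eta, grades


def metabolic_deviation(
    perturbed_state: FluxState,
    healthy_template: FluxState,
    disease_template: FluxState,
    monitored: Optional[Sequence[str]] = None,
    rel_band: float = 0.2,
    abs_floor: float = 1e-3,
) -> float:
    """Fuzzy metabolic-deviation grade of a perturbed healthy model.

    Per monitored flux: similarity = two-sided grade centered on the
    healthy-template flux; dissimilarity = 1 - two-sided grade centered on
    the disease-template flux.  eta_MD = (mean similarity + mean
    dissimilarity) / 2.  Infeasible perturbed model -> 0."""
    if not perturbed_state.feasible:
        return 0.0
    if not healthy_template.feasible or not disease_template.feasible:
        raise ValidationError("templates must be feasible flux states")
    ids = list(monitored) if monitored is not None else perturbed_state.reaction_ids
    p = perturbed_state.net_map()
    h = healthy_template.net_map()
    d = disease_template.net_map()
    for name, m in (("perturbed", p), ("healthy template", h), ("disease template", d)):
        missing = [rid for rid in ids if rid not in m]
        if missing:
            raise ValidationError(
                f"{name} state lacks monitored reaction(s): {missing[:5]}"
            )
    sims = []
    diss = []
    for rid in ids:
        sims.append(two_sided_band(h[rid], rel_band, abs_floor).grade(p[rid]))
        diss.append(1.0 - two_sided_band(d[rid], rel_band, abs_floor).grade(p[rid]))
    return 0.5 * (float(np.mean(sims)) + float(np.mean(diss)))


def fuzzy_decision(grades: Sequence[float], aggregation: str = "min") -> float:
    """Aggregate component grades into the decision score eta_D."""
    if len(grades) == 0:
        raise ValidationError("fuzzy decision needs at least one grade")
    if aggregation == "min":
        return float(min(grades))
    if aggregation == "mean":
        return float(np.mean(grades))
    raise ValidationError(f"unknown aggregation {aggregation!r}")


# ---------------------------------------------------------------------------
# Candidate evaluation over model pairs and media
# ---------------------------------------------------------------------------


@dataclass
class ModelPair:
    """One disease model and its healthy counterpart.

    ``protein_sense`` selects which registered protein reactions act as
    objectives ("synthesis" for cytokine-driven disease models,
    "degradation" for muscle-wasting models)."""

    name: str
    disease: MetabolicNetwork
    healthy: MetabolicNetwork
    disease_weights: Optional[Mapping[str, float]] = None
    healthy_weights: Optional[Mapping[str, float]] = None
    protein_sense: str = "synthesis"

    def objectives(self, network: MetabolicNetwork) -> list[Objective]:
        return default_objectives(network, protein_sense=self.protein_sense)


@dataclass
class ActdConfig:
    """Evaluation and search settings."""

    sigma: float = 1.0
    cv_aggregation: str = "min"
    decision_aggregation: str = "min"
    md_rel_band: float = 0.2
    md_abs_floor: float = 1e-3
    monitored_reactions: Optional[list[str]] = None
    paper_literal: bool = False
    # DE hyperparameters
    population: int = 20
    f_scale: float = 0.5
    crossover: float = 0.8
    generations: int = 200
    diversity_tol: float = 1e-3
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.population < 4:
            raise ValidationError("DE population must be >= 4")
        if not (0 < self.f_scale <= 2):
            raise ValidationError("DE scale factor must lie in (0, 2]")
        if not (0 <= self.crossover <= 1):
            raise ValidationError("DE crossover rate must lie in [0, 1]")


@dataclass
class EvaluationResult:
    """Fuzzy grades of one therapy candidate."""

    candidate: TherapyCandidate
    eta_cv: dict[tuple[str, str], float] = field(default_factory=dict)  # (model, medium)
    eta_md: dict[tuple[str, str], float] = field(default_factory=dict)
    objective_grades: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    infeasible_disease: set[tuple[str, str]] = field(default_factory=set)
    infeasible_healthy: set[tuple[str, str]] = field(default_factory=set)
    eta_d: float = float("nan")

    @property
    def mean_cv(self) -> float:
        return float(np.mean(list(self.eta_cv.values())))

    @property
    def mean_md(self) -> float:
        return float(np.mean(list(self.eta_md.values())))

    def cv_by_model(self) -> dict[str, float]:
        out: dict[str, list[float]] = {}
        for (model, _), v in self.eta_cv.items():
            out.setdefault(model, []).append(v)
        return {m: float(np.mean(v)) for m, v in out.items()}

    def md_by_model(self) -> dict[str, float]:
        out: dict[str, list[float]] = {}
        for (model, _), v in self.eta_md.items():
            out.setdefault(model, []).append(v)
        return {m: float(np.mean(v)) for m, v in out.items()}


class CandidateEvaluator:
    """Evaluates therapy candidates against model pairs across media,
    caching untreated templates and candidate scores."""

    def __init__(
        self,
        pairs: Sequence[ModelPair],
        media: Sequence[Medium],
        config: Optional[ActdConfig] = None,
    ) -> None:
        if not pairs:
            raise ValidationError("need at least one disease/healthy model pair")
        if not media:
            raise ValidationError("need at least one medium")
        self.pairs = list(pairs)
        self.media = list(media)
        self.config = config or ActdConfig()
        self._templates: dict[tuple[str, str, str], FluxState] = {}
        self._nets: dict[tuple[str, str, str], MetabolicNetwork] = {}
        self._cache: dict[tuple, EvaluationResult] = {}
        self.n_lp_evaluations = 0

    # -- templates --------------------------------------------------------

    def _medium_net(self, pair: ModelPair, which: str, medium: Medium) -> MetabolicNetwork:
        key = (pair.name, which, medium.name)
        if key not in self._nets:
            net = pair.disease if which == "disease" else pair.healthy
            self._nets[key] = apply_medium(net, medium)
        return self._nets[key]

    def template(self, pair: ModelPair, which: str, medium: Medium) -> FluxState:
        key = (pair.name, which, medium.name)
        if key not in self._templates:
            net = self._medium_net(pair, which, medium)
            weights = (
                pair.disease_weights if which == "disease" else pair.healthy_weights
            )
            self._templates[key] = pmofba(
                net,
                weights=weights,
                objectives=pair.objectives(net),
                sigma=self.config.sigma,
                paper_literal=self.config.paper_literal,
            )
            self.n_lp_evaluations += 1
        return self._templates[key]

    # -- evaluation -------------------------------------------------------

    def evaluate(self, candidate: TherapyCandidate) -> EvaluationResult:
        key = candidate.key()
        if key in self._cache:
            return self._cache[key]
        cfg = self.config
        result = EvaluationResult(candidate=candidate)
        component_grades: list[float] = []
        for pair in self.pairs:
            for medium in self.media:
                dnet = self._medium_net(pair, "disease", medium)
                hnet = self._medium_net(pair, "healthy", medium)
                objectives = pair.objectives(dnet)
                ca_template = self.template(pair, "disease", medium)
                ht_template = self.template(pair, "healthy", medium)
                if not ca_template.feasible or not ht_template.feasible:
                    raise ValidationError(
                        f"untreated model pair {pair.name!r} infeasible in "
                        f"medium {medium.name!r}; check the medium panel"
                    )
                fns = default_cv_membership(ca_template.zstar)

                treated = apply_candidate(
                    dnet, candidate, reference_flux=ca_template.net_map()
                )
                t_state = pmofba(
                    treated,
                    weights=pair.disease_weights,
                    objectives=objectives,
                    sigma=cfg.sigma,
                    paper_literal=cfg.paper_literal,
                )
                self.n_lp_evaluations += 1
                cv, grades = cell_viability(
                    t_state, objectives, fns, aggregation=cfg.cv_aggregation
                )
                mkey = (pair.name, medium.name)
                result.eta_cv[mkey] = cv
                result.objective_grades[mkey] = grades
                if not t_state.feasible:
                    result.infeasible_disease.add(mkey)

                perturbed = apply_candidate(
                    hnet, candidate, reference_flux=ht_template.net_map()
                )
                p_state = pmofba(
                    perturbed,
                    weights=pair.healthy_weights,
                    objectives=pair.objectives(hnet),
                    sigma=cfg.sigma,
                    paper_literal=cfg.paper_literal,
                )
                self.n_lp_evaluations += 1
                md = metabolic_deviation(
                    p_state,
                    ht_template,
                    ca_template,
                    monitored=cfg.monitored_reactions,
                    rel_band=cfg.md_rel_band,
                    abs_floor=cfg.md_abs_floor,
                )
                if not p_state.feasible:
                    result.infeasible_healthy.add(mkey)
                result.eta_md[mkey] = md
                component_grades.extend([cv, md])
        result.eta_d = fuzzy_decision(
            component_grades, aggregation=cfg.decision_aggregation
        )
        self._cache[key] = result
        return result


def evaluate_candidate(
    candidate: TherapyCandidate,
    pairs: Sequence[ModelPair],
    media: Sequence[Medium],
    config: Optional[ActdConfig] = None,
) -> EvaluationResult:
    """One-shot evaluation (builds a throwaway evaluator)."""
    return CandidateEvaluator(pairs, media, config).evaluate(candidate)


# ---------------------------------------------------------------------------
# Search space and nested hybrid differential evolution
# ---------------------------------------------------------------------------


@dataclass
class SearchSpace:
    """Finite intervention space: targets are gene sets (complexes count as
    one target) with allowed modes; candidates combine 1..max_size disjoint
    targets."""

    targets: list[frozenset[str]]
    modes: dict[frozenset[str], tuple[str, ...]] = field(default_factory=dict)
    max_size: int = 2
    magnitude: float = 2.0

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValidationError("empty search space")
        if self.max_size not in (1, 2):
            raise ValidationError("candidate size must be 1 or 2")
        if self.magnitude <= 1:
            raise ValidationError("upregulation magnitude must be > 1")
        for t in self.targets:
            self.modes.setdefault(t, ("knockout", "upregulation"))

    def options(self) -> list[TargetModification]:
        """Flat list of (target, mode) interventions, deterministic order."""
        out = []
        for target in sorted(self.targets, key=lambda t: tuple(sorted(t))):
            for mode in self.modes[target]:
                out.append(
                    TargetModification(
                        kind=mode,
                        genes=target,
                        magnitude=self.magnitude if mode == "upregulation" else None,
                    )
                )
        return out

    def enumerate_candidates(self) -> list[TherapyCandidate]:
        """All singles (and pairs with disjoint genes, if max_size is 2)."""
        opts = self.options()
        cands = [TherapyCandidate((m,)) for m in opts]
        if self.max_size == 2:
            for a, b in combinations(opts, 2):
                if a.genes & b.genes:
                    continue
                cands.append(TherapyCandidate((a, b)))
        return cands


def _decode(vector: np.ndarray, options: list[TargetModification]) -> TherapyCandidate:
    """Round a continuous slot vector to a candidate; slot value len(options)
    means 'empty slot'; overlapping or duplicate targets drop the later slot."""
    n_opts = len(options)
    mods: list[TargetModification] = []
    used: set[frozenset[str]] = set()
    genes: set[str] = set()
    for raw in vector:
        idx = int(np.clip(np.rint(raw), 0, n_opts))
        if idx == n_opts:
            continue
        mod = options[idx]
        if mod.genes in used or (mod.genes & genes):
            continue
        mods.append(mod)
        used.add(mod.genes)
        genes |= mod.genes
    return TherapyCandidate(tuple(mods))


@dataclass
class RankedCandidate:
    candidate: TherapyCandidate
    result: EvaluationResult

    @property
    def eta_d(self) -> float:
        return self.result.eta_d


def nested_hde(
    space: SearchSpace,
    pairs: Sequence[ModelPair],
    media: Sequence[Medium],
    config: Optional[ActdConfig] = None,
    seed: Optional[int] = None,
    evaluator: Optional[CandidateEvaluator] = None,
) -> list[RankedCandidate]:
    """Nested hybrid differential evolution over the candidate space.

    Outer level: DE/rand/1/bin on continuous slot vectors rounded to
    intervention indices, with greedy selection (elitist) and a migration
    operator that re-seeds all but the best individual when the population
    diversity collapses.  Inner level: every fitness evaluation runs the
    parsimonious multi-objective LPs via :class:`CandidateEvaluator`.
    Deterministic for a fixed seed.  Returns all evaluated candidates
    ranked by eta_D (ties broken by candidate key)."""
    cfg = config or ActdConfig()
    if seed is None:
        seed = cfg.seed
    if seed is None:
        raise ValidationError("nested_hde requires a seed")
    rng = np.random.default_rng(int(seed))
    evaluator = evaluator or CandidateEvaluator(pairs, media, cfg)
    options = space.options()
    n_opts = len(options)
    dim = space.max_size
    lo, hi = -0.49, n_opts + 0.49  # n_opts encodes the empty slot

    seen: dict[tuple, EvaluationResult] = {}

    def fitness(vec: np.ndarray) -> tuple[float, TherapyCandidate, EvaluationResult]:
        cand = _decode(vec, options)
        res = evaluator.evaluate(cand)
        seen[cand.key()] = res
        return res.eta_d, cand, res

    pop = rng.uniform(lo, hi, size=(cfg.population, dim))
    fit = np.empty(cfg.population)
    keys: list[tuple] = [None] * cfg.population  # type: ignore[list-item]
    for i in range(cfg.population):
        fit[i], cand, _ = fitness(pop[i])
        keys[i] = cand.key()

    for _gen in range(cfg.generations):
        for i in range(cfg.population):
            r1, r2, r3 = _distinct_indices(rng, cfg.population, i)
            mutant = pop[r1] + cfg.f_scale * (pop[r2] - pop[r3])
            trial = pop[i].copy()
            jrand = rng.integers(dim)
            for j in range(dim):
                if rng.random() < cfg.crossover or j == jrand:
                    trial[j] = mutant[j]
            trial = np.clip(trial, lo, hi)
            f_trial, cand, _ = fitness(trial)
            if f_trial >= fit[i]:
                pop[i] = trial
                fit[i] = f_trial
                keys[i] = cand.key()
        # migration / restart on diversity collapse, measured both in the
        # continuous genotype and in the decoded candidate space
        diversity = float(np.mean(np.std(pop, axis=0)))
        distinct = len(set(keys))
        if diversity < cfg.diversity_tol or distinct <= max(2, cfg.population // 4):
            best = int(np.argmax(fit))
            keep_vec, keep_fit, keep_key = pop[best].copy(), fit[best], keys[best]
            pop = rng.uniform(lo, hi, size=(cfg.population, dim))
            pop[0], fit[0], keys[0] = keep_vec, keep_fit, keep_key
            for i in range(1, cfg.population):
                fit[i], cand, _ = fitness(pop[i])
                keys[i] = cand.key()

    ranked = [
        RankedCandidate(candidate=res.candidate, result=res) for res in seen.values()
    ]
    ranked.sort(key=lambda rc: (-rc.eta_d, rc.candidate.key()))
    return ranked


def _distinct_indices(rng: np.random.Generator, n: int, exclude: int) -> tuple[int, int, int]:
    idx = [i for i in range(n) if i != exclude]
    picks = rng.choice(len(idx), size=3, replace=False)
    return tuple(idx[p] for p in picks)  # type: ignore[return-value]


def medium_independence_filter(
    results: Sequence[RankedCandidate] | Sequence[EvaluationResult],
    threshold: float,
) -> list:
    """Keep candidates whose eta_CV is >= threshold in every medium for
    every disease model (medium-independent efficacy)."""
    kept = []
    for item in results:
        res = item.result if isinstance(item, RankedCandidate) else item
        if res.eta_cv and all(v >= threshold for v in res.eta_cv.values()):
            kept.append(item)
    return kept
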