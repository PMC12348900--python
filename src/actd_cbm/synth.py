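"""Seeded toy-world generator.

Builds a pair of small disease/healthy metabolic networks with the
structural features the analysis stack needs — a biomass drain, an ATP
hydrolysis (maintenance) reaction, glucose/ammonium exchanges, AND/OR GPR
rules, optional lumped protein turnover — plus grouped expression tables
with planted quartile structure, a panel of nutritional media, and planted
ground truths:

* a *lethal* gene: the disease cell's sole glucose transporter (the
  healthy cell imports glucose through a different transporter), so its
  knockout starves the disease cell while leaving healthy flux untouched;
* *biomarker* metabolites: lower-bound-forced synthesis routes present
  only in the disease network (complete-increase markers) or only in the
  healthy network (complete-decrease markers), which guarantees disjoint
  flow envelopes in every medium.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from actd_cbm.core import (
    Medium,
    MetabolicNetwork,
    ObjectiveRegistry,
    Reaction,
    Species,
    TargetModification,
    TherapyCandidate,
    ValidationError,
)
from actd_cbm.core import GprRule
from actd_cbm.actd import ModelPair, SearchSpace
from actd_cbm.expression import ExpressionProfile, classify_genes, reaction_confidence
from actd_cbm.proteins import ProteinSpec, extend_network

DISEASE = "disease"
HEALTHY = "healthy"

_CLASS_LEVELS = {"high": 30.0, "medium": 6.0, "none": 1.5, "negative": 0.3}


@dataclass
class ToyWorldConfig:
    """Knobs of the generated world; defaults are the study conditions."""

    seed: int = 0
    n_media: int = 5
    n_pathway_branches: int = 2  # parallel glycolytic branches
    n_internal_metabolites: int = 2  # respiration-chain intermediates
    n_genes: int = 12
    include_protein_module: bool = True
    planted_lethal_gene: Optional[str] = "gT"
    planted_biomarkers: list[tuple[str, str]] = field(
        default_factory=lambda: [("bmk", "increase"), ("hmk", "decrease")]
    )
    include_starvation_medium: bool = False
    disease_maintenance: float = 3.0  # forced ATP hydrolysis, mmol/gDW/h
    healthy_maintenance: float = 1.0
    forced_marker_flux: float = 2.0
    # forced flux on the last glycolytic branch; distinct values keep the
    # disease and healthy templates separated on that flux, so perturbing
    # it always costs similarity
    basal_branch_flux: float = 0.1
    disease_basal_branch_flux: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("toy world requires a seed")
        if self.n_media < 1 or self.n_pathway_branches < 1:
            raise ValidationError("sizes must be positive")
        if self.n_internal_metabolites < 1:
            raise ValidationError("sizes must be positive")


@dataclass
class ToyWorld:
    """The generated world plus its planted ground truth."""

    config: ToyWorldConfig
    disease: MetabolicNetwork
    healthy: MetabolicNetwork
    expression: dict[str, ExpressionProfile]
    media: list[Medium]
    search_space: SearchSpace
    disease_weights: dict[str, float]
    healthy_weights: dict[str, float]
    ground_truth: dict

    @property
    def model_pair(self) -> ModelPair:
        return ModelPair(
            name="toy",
            disease=self.disease,
            healthy=self.healthy,
            disease_weights=self.disease_weights,
            healthy_weights=self.healthy_weights,
            protein_sense="synthesis",
        )


def _gpr(text: str) -> GprRule:
    rule = GprRule.from_string(text)
    assert rule is not None
    return rule


def _base_species() -> list[Species]:
    comp = []
    for sid, name, c in [
        ("glc__D_e", "D-glucose", "e"),
        ("glc__D_c", "D-glucose", "c"),
        ("nh4_e", "ammonium", "e"),
        ("nh4_c", "ammonium", "c"),
        ("pyr_c", "pyruvate", "c"),
        ("co2_c", "CO2", "c"),
        ("co2_e", "CO2", "e"),
        ("atp_c", "ATP", "c"),
        ("adp_c", "ADP", "c"),
        ("pi_c", "phosphate", "c"),
        ("pi_e", "phosphate", "e"),
        ("h_c", "proton", "c"),
        ("h_e", "proton", "e"),
        ("h2o_c", "water", "c"),
        ("h2o_e", "water", "e"),
        ("ala__L_c", "L-alanine", "c"),
        ("gly_c", "glycine", "c"),
    ]:
        comp.append(Species(id=sid, name=name, compartment=c))
    return comp


def _exchange(sid: str, uptake: float = 0.0) -> Reaction:
    return Reaction(
        id=f"EX_{sid}",
        name=f"{sid} exchange",
        stoichiometry={sid: -1.0},
        lb_f=0.0,
        ub_f=1000.0,
        lb_b=0.0,
        ub_b=uptake,
        is_exchange=True,
    )


def _build_network(
    config: ToyWorldConfig, condition: str, rng: np.random.Generator
) -> MetabolicNetwork:
    """One network of the pair; disease and healthy share the reaction set
    and differ only in bounds (transporter availability, maintenance load,
    forced biomarker routes)."""
    species = _base_species()
    reactions: list[Reaction] = []

    # exchanges (uptake caps are applied later through media)
    for sid in ["glc__D_e", "nh4_e", "pi_e", "h_e", "h2o_e", "co2_e"]:
        uptake = 1000.0 if sid in ("pi_e", "h_e", "h2o_e") else 10.0
        reactions.append(_exchange(sid, uptake=uptake))

    is_disease = condition == DISEASE

    # glucose transport: the disease cell depends exclusively on the gT
    # transporter, the healthy cell exclusively on gALT
    reactions.append(
        Reaction(
            id="GLCt",
            name="glucose transport (disease-dependent)",
            stoichiometry={"glc__D_e": -1.0, "glc__D_c": 1.0},
            ub_f=1000.0 if is_disease else 0.0,
            gpr=_gpr("gT"),
        )
    )
    reactions.append(
        Reaction(
            id="GLCt_alt",
            name="glucose transport (healthy-dependent)",
            stoichiometry={"glc__D_e": -1.0, "glc__D_c": 1.0},
            ub_f=0.0 if is_disease else 1000.0,
            gpr=_gpr("gALT"),
        )
    )
    reactions.append(
        Reaction(
            id="NH4t",
            name="ammonium transport",
            stoichiometry={"nh4_e": -1.0, "nh4_c": 1.0},
        )
    )
    for sid_e, sid_c, rid in [
        ("pi_e", "pi_c", "PIt"),
        ("h_e", "h_c", "Ht"),
        ("h2o_e", "h2o_c", "H2Ot"),
    ]:
        reactions.append(
            Reaction(
                id=rid,
                name=f"{sid_c} transport",
                stoichiometry={sid_e: -1.0, sid_c: 1.0},
                ub_f=1000.0,
                ub_b=1000.0,
            )
        )
    reactions.append(
        Reaction(
            id="CO2t",
            name="CO2 export",
            stoichiometry={"co2_c": -1.0, "co2_e": 1.0},
        )
    )

    # parallel glycolytic branches with decreasing ATP yield; the first is
    # isozyme-backed (OR rule), the last carries a forced basal flux
    n_branches = config.n_pathway_branches
    branch_genes: list[str] = []
    for b in range(n_branches):
        yield_atp = max(2 - b, 1)
        if b == 0:
            gpr = _gpr("gA1 or gA2")
            branch_genes += ["gA1", "gA2"]
        elif b == 1:
            gpr = _gpr("gB")
            branch_genes.append("gB")
        else:
            gene = f"gC{b}"
            gpr = _gpr(gene)
            branch_genes.append(gene)
        basal = (
            config.disease_basal_branch_flux if is_disease else config.basal_branch_flux
        )
        lb = basal if b == n_branches - 1 and n_branches > 1 else 0.0
        reactions.append(
            Reaction(
                id=f"GLY{b + 1}",
                name=f"glycolytic branch {b + 1}",
                stoichiometry={
                    "glc__D_c": -1.0,
                    "adp_c": -float(yield_atp),
                    "pi_c": -float(yield_atp),
                    "pyr_c": 2.0,
                    "atp_c": float(yield_atp),
                    "h2o_c": float(yield_atp),
                },
                lb_f=lb,
                gpr=gpr,
            )
        )

    # respiration chain through n_internal_metabolites intermediates,
    # catalyzed by the gR1-gR2 complex
    chain = ["pyr_c"] + [f"im{i}_c" for i in range(1, config.n_internal_metabolites)]
    for sid in chain[1:]:
        species.append(Species(id=sid, name=f"intermediate {sid}", compartment="c"))
    for i, src in enumerate(chain):
        dst = chain[i + 1] if i + 1 < len(chain) else None
        stoich: dict[str, float] = {src: -1.0}
        if dst is not None:
            stoich[dst] = 1.0
            rid = f"RESPc{i + 1}"
            reactions.append(Reaction(id=rid, name=f"respiration step {i + 1}", stoichiometry=stoich))
        else:
            stoich.update(
                {
                    "adp_c": -3.0,
                    "pi_c": -3.0,
                    "atp_c": 3.0,
                    "co2_c": 1.0,
                    "h2o_c": 3.0,
                }
            )
            reactions.append(
                Reaction(
                    id="RESP",
                    name="respiration (lumped)",
                    stoichiometry=stoich,
                    gpr=_gpr("gR1 and gR2"),
                )
            )

    # amino-acid synthesis (shared gene gS) and the biomass drain
    reactions.append(
        Reaction(
            id="ALAS",
            name="alanine synthesis",
            stoichiometry={
                "pyr_c": -1.0,
                "nh4_c": -1.0,
                "atp_c": -1.0,
                "h2o_c": -1.0,
                "ala__L_c": 1.0,
                "adp_c": 1.0,
                "pi_c": 1.0,
                "h_c": 1.0,
            },
            gpr=_gpr("gS"),
        )
    )
    reactions.append(
        Reaction(
            id="GLYS",
            name="glycine synthesis",
            stoichiometry={
                "pyr_c": -1.0,
                "nh4_c": -1.0,
                "atp_c": -1.0,
                "h2o_c": -1.0,
                "gly_c": 1.0,
                "co2_c": 1.0,
                "adp_c": 1.0,
                "pi_c": 1.0,
                "h_c": 1.0,
            },
            gpr=_gpr("gS"),
        )
    )
    # biomass composition and energy demand differ between the conditions
    # (cancer anabolism is alanine- and ATP-hungry here); this keeps the
    # two untreated flux templates separated on the whole growth machinery,
    # not just on the transporter and marker routes
    ala, gly, atp_cost = (0.8, 0.2, 3.0) if is_disease else (0.4, 0.6, 1.5)
    reactions.append(
        Reaction(
            id="BIOMASS",
            name="biomass drain",
            stoichiometry={
                "ala__L_c": -ala,
                "gly_c": -gly,
                "atp_c": -atp_cost,
                "h2o_c": -atp_cost,
                "adp_c": atp_cost,
                "pi_c": atp_cost,
                "h_c": atp_cost,
            },
        )
    )
    maintenance = (
        config.disease_maintenance if is_disease else config.healthy_maintenance
    )
    reactions.append(
        Reaction(
            id="ATPM",
            name="ATP maintenance (hydrolysis)",
            stoichiometry={
                "atp_c": -1.0,
                "h2o_c": -1.0,
                "adp_c": 1.0,
                "pi_c": 1.0,
                "h_c": 1.0,
            },
            lb_f=maintenance,
        )
    )

    # planted biomarker routes: lb-forced synthesis + secretion, active in
    # exactly one of the two conditions
    marker_genes = {"increase": "gX", "decrease": "gY"}
    seen_markers: set[str] = set()
    for idx, (base, direction) in enumerate(config.planted_biomarkers):
        if direction not in ("increase", "decrease"):
            raise ValidationError(
                f"planted biomarker {base!r}: direction must be increase/decrease"
            )
        if base in seen_markers:
            raise ValidationError(f"planted biomarker {base!r} listed twice")
        seen_markers.add(base)
        cid, eid = f"{base}_c", f"{base}_e"
        if cid in {s.id for s in species}:
            raise ValidationError(f"planted biomarker {base!r} collides with a species")
        species.append(Species(id=cid, name=base, compartment="c"))
        species.append(Species(id=eid, name=base, compartment="e"))
        active = is_disease if direction == "increase" else not is_disease
        gene = marker_genes[direction] if idx < 2 else f"gM{idx}"
        reactions.append(
            Reaction(
                id=f"{base.upper()}S",
                name=f"{base} synthesis (forced)",
                stoichiometry={"pyr_c": -1.0, cid: 1.0},
                lb_f=config.forced_marker_flux if active else 0.0,
                ub_f=1000.0 if active else 0.0,
                gpr=_gpr(gene),
            )
        )
        reactions.append(
            Reaction(
                id=f"{base.upper()}t",
                name=f"{base} export",
                stoichiometry={cid: -1.0, eid: 1.0},
            )
        )
        reactions.append(_exchange(eid))

    objectives = ObjectiveRegistry(biomass="BIOMASS", atp="ATPM")
    net = MetabolicNetwork(
        species=species,
        reactions=reactions,
        objectives=objectives,
        id=f"toy_{condition}",
    )
    if config.include_protein_module:
        seq = "".join(rng.choice(["A", "G"], size=12))
        net = extend_network(net, [ProteinSpec(name="CYTK", sequence=seq, k_atp=4.0)])
    return net


def _gene_catalogue(network: MetabolicNetwork, config: ToyWorldConfig) -> list[str]:
    genes = sorted(network.genes)
    fillers = [f"gZ{i}" for i in range(1, max(0, config.n_genes - len(genes)) + 1)]
    return genes + fillers


def make_expression(
    config: ToyWorldConfig, genes: Optional[list[str]] = None
) -> dict[str, ExpressionProfile]:
    """Expression tables with planted quartile membership per condition.

    Disease overexpresses its transporter/marker genes; the healthy
    condition mirrors the pattern.  Log-normal jitter (seeded) preserves
    the planted class ordering because the class base levels are separated
    by more than the jitter range."""
    rng = np.random.default_rng(config.seed + 1)
    if genes is None:
        world_rng = np.random.default_rng(config.seed)
        genes = _gene_catalogue(_build_network(config, DISEASE, world_rng), config)
    n = len(genes)
    quarter = n // 4

    def planted(condition: str) -> dict[str, str]:
        priority_high = (
            ["gT", "gA1", "gX"] if condition == DISEASE else ["gALT", "gA2", "gY"]
        )
        priority_low = (
            ["gALT", "gA2", "gY"] if condition == DISEASE else ["gT", "gX", "gA1"]
        )
        rest = [g for g in genes if g not in priority_high + priority_low]
        ordered = (
            [g for g in priority_high if g in genes]
            + rest
            + [g for g in priority_low if g in genes]
        )
        classes = {}
        for i, gene in enumerate(ordered):
            if i < quarter:
                classes[gene] = "high"
            elif i < 2 * quarter:
                classes[gene] = "medium"
            elif i < n - quarter:
                classes[gene] = "none"
            else:
                classes[gene] = "negative"
        return classes

    profiles = {}
    for condition in (DISEASE, HEALTHY):
        classes = planted(condition)
        values = {}
        for gene in genes:
            base = _CLASS_LEVELS[classes[gene]]
            values[gene] = float(base * np.exp(rng.normal(0.0, 0.15)))
        profiles[condition] = ExpressionProfile(values=values, condition=condition)
    return profiles


def make_media_panel(config: ToyWorldConfig) -> list[Medium]:
    """Media varying the carbon/nitrogen uptake caps; all feasible by
    construction (caps stay above the forced loads)."""
    rng = np.random.default_rng(config.seed + 2)
    media = []
    base_glc = np.array([10.0, 8.0, 12.0, 15.0, 20.0])
    base_nh4 = np.array([10.0, 10.0, 8.0, 12.0, 15.0])
    for i in range(config.n_media):
        glc = float(base_glc[i % 5] * (1.0 + 0.1 * rng.uniform(-1, 1)) + 2.0 * (i // 5))
        nh4 = float(base_nh4[i % 5] * (1.0 + 0.1 * rng.uniform(-1, 1)) + 1.0 * (i // 5))
        media.append(
            Medium(
                name=f"medium_{i + 1}",
                uptake_bounds={
                    "EX_glc__D_e": glc,
                    "EX_nh4_e": nh4,
                    "EX_pi_e": 1000.0,
                    "EX_h_e": 1000.0,
                    "EX_h2o_e": 1000.0,
                },
            )
        )
    if config.include_starvation_medium:
        media.append(
            Medium(
                name="starvation",
                uptake_bounds={"EX_pi_e": 1000.0, "EX_h_e": 1000.0, "EX_h2o_e": 1000.0},
            )
        )
    return media


def make_toy_world(config: Optional[ToyWorldConfig] = None) -> ToyWorld:
    """Generate the full world: network pair, expression, media, search
    space and planted ground truth.  Deterministic for a fixed seed."""
    config = config or ToyWorldConfig()
    rng = np.random.default_rng(config.seed)
    disease = _build_network(config, DISEASE, rng)
    rng = np.random.default_rng(config.seed)  # same protein sequence in both
    healthy = _build_network(config, HEALTHY, rng)

    genes = _gene_catalogue(disease, config)
    expression = make_expression(config, genes=genes)
    media = make_media_panel(config)

    disease_weights = reaction_confidence(
        disease, classify_genes(expression[DISEASE])
    ).weights
    healthy_weights = reaction_confidence(
        healthy, classify_genes(expression[HEALTHY])
    ).weights

    targets = [
        frozenset(["gT"]),
        frozenset(["gALT"]),
        frozenset(["gB"]),
        frozenset(["gS"]),
        frozenset(["gR1", "gR2"]),  # enzyme complex as one target
    ]
    space = SearchSpace(
        targets=targets,
        modes={
            frozenset(["gT"]): ("knockout",),
            frozenset(["gALT"]): ("knockout",),
            frozenset(["gB"]): ("knockout", "upregulation"),
            frozenset(["gS"]): ("knockout", "upregulation"),
            frozenset(["gR1", "gR2"]): ("knockout",),
        },
        max_size=2,
    )

    lethal = config.planted_lethal_gene
    optimal = (
        TherapyCandidate((TargetModification("knockout", frozenset([lethal])),))
        if lethal
        else None
    )
    marker_truth = {
        f"{base}_c": ("CI" if direction == "increase" else "CD")
        for base, direction in config.planted_biomarkers
    }
    ground_truth = {
        "planted_lethal_gene": lethal,
        "optimal_candidate": optimal,
        "planted_biomarkers": marker_truth,
    }
    return ToyWorld(
        config=config,
        disease=disease,
        healthy=healthy,
        expression=expression,
        media=media,
        search_space=space,
        disease_weights=disease_weights,
        healthy_weights=healthy_weights,
        ground_truth=ground_truth,
    )
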