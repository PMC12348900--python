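"""Network data model for constraint-based target discovery.

The in-memory representation splits every reaction into two irreversible
flux variables ``vf, vb >= 0`` so that the weighted total-flux objective
``sum_i w_i (vf_i + vb_i)`` is linear; the net flux reported to users is
``vf - vb``.  SBML Level 3 (+fbc) I/O is delegated to cobrapy; this module
owns the split-bound convention, GPR evaluation, medium application and
intervention (knockout / upregulation) application.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import sparse

DEFAULT_SECRETION_CAP = 1000.0
"""Conventional 'unbounded' sentinel for open exchange directions."""


class ValidationError(ValueError):
    """An object violates a structural invariant of the data model."""


class FormatError(ValueError):
    """An input file could not be parsed into a valid object."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GprRule:
    """Boolean gene-protein-reaction rule.

    ``op`` is one of ``"gene"`` (leaf), ``"and"`` (enzyme complex: every
    subunit required) or ``"or"`` (isozymes: any suffices).
    """

    op: str
    gene: Optional[str] = None
    children: tuple["GprRule", ...] = ()

    def __post_init__(self) -> None:
        if self.op == "gene":
            if not self.gene:
                raise ValidationError("GPR leaf must carry a gene id")
            if self.children:
                raise ValidationError("GPR leaf cannot have children")
        elif self.op in ("and", "or"):
            if len(self.children) < 1:
                raise ValidationError(f"GPR {self.op!r} node needs children")
        else:
            raise ValidationError(f"unknown GPR node type {self.op!r}")

    @property
    def genes(self) -> frozenset[str]:
        if self.op == "gene":
            return frozenset([self.gene])  # type: ignore[list-item]
        out: set[str] = set()
        for child in self.children:
            out |= child.genes
        return frozenset(out)

    def is_active(self, knocked: frozenset[str] | set[str]) -> bool:
        if self.op == "gene":
            return self.gene not in knocked
        if self.op == "and":
            return all(c.is_active(knocked) for c in self.children)
        return any(c.is_active(knocked) for c in self.children)

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        joiner = f" {self.op} "
        parts = []
        for child in self.children:
            s = child.to_string()
            if child.op != "gene":
                s = f"({s})"
            parts.append(s)
        return joiner.join(parts)

    @classmethod
    def from_string(cls, text: str) -> Optional["GprRule"]:
        """Parse a boolean rule string ('g1 and (g2 or g3)') via cobrapy."""
        text = (text or "").strip()
        if not text:
            return None
        import ast

        from cobra.core.gene import GPR

        try:
            gpr = GPR.from_string(text)
        except Exception as exc:  # cobra raises bare exceptions on bad syntax
            raise FormatError(f"cannot parse GPR rule {text!r}: {exc}") from exc
        if gpr.body is None:
            return None

        def convert(node: "ast.AST") -> "GprRule":
            if isinstance(node, ast.Name):
                return cls(op="gene", gene=node.id)
            if isinstance(node, ast.BoolOp):
                op = "and" if isinstance(node.op, ast.And) else "or"
                return cls(op=op, children=tuple(convert(v) for v in node.values))
            raise FormatError(f"unsupported GPR syntax element {node!r} in {text!r}")

        return convert(gpr.body)


def eval_gpr(
    rule: Optional[GprRule],
    knocked_genes: Iterable[str],
    known_genes: Optional[Iterable[str]] = None,
) -> bool:
    """Evaluate whether a reaction remains catalyzed given knocked-out genes.

    A reaction without a rule is always active.  Gene ids in
    ``knocked_genes`` that are not in ``known_genes`` (when provided)
    trigger a warning and are ignored semantically (they cannot match any
    leaf anyway).
    """
    knocked = frozenset(knocked_genes)
    if known_genes is not None:
        unknown = knocked - frozenset(known_genes)
        if unknown:
            warnings.warn(
                f"knocked gene(s) not present in the network: {sorted(unknown)}",
                stacklevel=2,
            )
    if rule is None:
        return True
    return rule.is_active(knocked)


# ---------------------------------------------------------------------------
# Species / reactions / network
# ---------------------------------------------------------------------------


@dataclass
class Species:
    """A metabolite located in a specific cellular compartment."""

    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None
    molar_mass: Optional[float] = None  # g/mmol

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("species id must be non-empty")
        if not self.compartment:
            raise ValidationError(f"species {self.id!r}: compartment must be non-empty")


@dataclass
class Reaction:
    """A reaction with split irreversible flux bounds.

    ``lb_f <= vf <= ub_f`` bounds the forward direction and
    ``lb_b <= vb <= ub_b`` the backward direction; both directions are
    nonnegative.  An irreversible reaction has ``ub_b == 0``.  Exchange
    reactions follow the export convention ``species_e ->`` (forward =
    secretion, backward = uptake).
    """

    id: str
    stoichiometry: dict[str, float]
    lb_f: float = 0.0
    ub_f: float = DEFAULT_SECRETION_CAP
    lb_b: float = 0.0
    ub_b: float = 0.0
    gpr: Optional[GprRule] = None
    is_exchange: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("reaction id must be non-empty")
        for lo, hi, side in ((self.lb_f, self.ub_f, "forward"), (self.lb_b, self.ub_b, "backward")):
            if not (0 <= lo <= hi):
                raise ValidationError(
                    f"reaction {self.id!r}: {side} bounds must satisfy 0 <= lb <= ub, got [{lo}, {hi}]"
                )
        if not self.stoichiometry and not self.is_exchange:
            raise ValidationError(f"reaction {self.id!r}: empty stoichiometry")

    @property
    def reversible(self) -> bool:
        return self.ub_b > 0

    @property
    def net_bounds(self) -> tuple[float, float]:
        """Signed net-flux bounds [lb_f - ub_b, ub_f - lb_b]."""
        return (self.lb_f - self.ub_b, self.ub_f - self.lb_b)

    def knock_out(self) -> None:
        self.lb_f = self.ub_f = self.lb_b = self.ub_b = 0.0

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lb_f=self.lb_f,
            ub_f=self.ub_f,
            lb_b=self.lb_b,
            ub_b=self.ub_b,
            gpr=self.gpr,
            is_exchange=self.is_exchange,
            name=self.name,
        )


def split_bounds(lb: float, ub: float) -> tuple[float, float, float, float]:
    """Split signed net bounds [lb, ub] into (lb_f, ub_f, lb_b, ub_b)."""
    if lb > ub:
        raise ValidationError(f"net bounds inverted: [{lb}, {ub}]")
    return (max(lb, 0.0), max(ub, 0.0), max(-ub, 0.0), max(-lb, 0.0))


@dataclass
class ObjectiveRegistry:
    """Named objective reactions: biomass, ATP hydrolysis, and per-protein
    synthesis / degradation reactions."""

    biomass: Optional[str] = None
    atp: Optional[str] = None
    protein_synthesis: dict[str, str] = field(default_factory=dict)
    protein_degradation: dict[str, str] = field(default_factory=dict)

    def roles(self) -> dict[str, str]:
        """Map reaction id -> role tag (used for SBML notes round-trip)."""
        out: dict[str, str] = {}
        if self.biomass:
            out[self.biomass] = "biomass"
        if self.atp:
            out[self.atp] = "atp"
        for name, rid in self.protein_synthesis.items():
            out[rid] = f"protein_synthesis:{name}"
        for name, rid in self.protein_degradation.items():
            out[rid] = f"protein_degradation:{name}"
        return out

    @classmethod
    def from_roles(cls, roles: Mapping[str, str]) -> "ObjectiveRegistry":
        reg = cls()
        for rid, role in roles.items():
            if role == "biomass":
                reg.biomass = rid
            elif role == "atp":
                reg.atp = rid
            elif role.startswith("protein_synthesis:"):
                reg.protein_synthesis[role.split(":", 1)[1]] = rid
            elif role.startswith("protein_degradation:"):
                reg.protein_degradation[role.split(":", 1)[1]] = rid
        return reg

    def copy(self) -> "ObjectiveRegistry":
        return ObjectiveRegistry(
            biomass=self.biomass,
            atp=self.atp,
            protein_synthesis=dict(self.protein_synthesis),
            protein_degradation=dict(self.protein_degradation),
        )


class MetabolicNetwork:
    """A stoichiometric system with split fluxes, bounds and GPR rules."""

    def __init__(
        self,
        species: Sequence[Species],
        reactions: Sequence[Reaction],
        objectives: Optional[ObjectiveRegistry] = None,
        id: str = "network",
    ) -> None:
        self.id = id
        self.species = list(species)
        self.reactions = list(reactions)
        self.objectives = objectives or ObjectiveRegistry()
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        for sp in self.species:
            if sp.id in seen:
                raise ValidationError(f"duplicate species id {sp.id!r}")
            seen.add(sp.id)
        rseen: set[str] = set()
        for rxn in self.reactions:
            if rxn.id in rseen:
                raise ValidationError(f"duplicate reaction id {rxn.id!r}")
            rseen.add(rxn.id)
            missing = set(rxn.stoichiometry) - seen
            if missing:
                raise ValidationError(
                    f"reaction {rxn.id!r} references unknown species {sorted(missing)}"
                )
        for rid in self.objectives.roles():
            if rid not in rseen:
                raise ValidationError(f"objective reaction {rid!r} not in network")

    # -- lookups ----------------------------------------------------------

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for rxn in self.reactions:
            if rxn.gpr is not None:
                out |= rxn.gpr.genes
        return frozenset(out)

    def get_species(self, sid: str) -> Species:
        for sp in self.species:
            if sp.id == sid:
                return sp
        raise KeyError(f"species {sid!r} not in network")

    def get_reaction(self, rid: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rid:
                return rxn
        raise KeyError(f"reaction {rid!r} not in network")

    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def reaction_index(self) -> dict[str, int]:
        return {r.id: j for j, r in enumerate(self.reactions)}

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """Signed stoichiometric matrix N (species x reactions)."""
        sidx = self.species_index()
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions):
            for sid, coeff in rxn.stoichiometry.items():
                rows.append(sidx[sid])
                cols.append(j)
                vals.append(float(coeff))
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.species), len(self.reactions))
        )

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            species=[replace(s) for s in self.species],
            reactions=[r.copy() for r in self.reactions],
            objectives=self.objectives.copy(),
            id=self.id,
        )

    def __repr__(self) -> str:
        return (
            f"<MetabolicNetwork {self.id!r}: {len(self.species)} species, "
            f"{len(self.reactions)} reactions, {len(self.genes)} genes>"
        )


# ---------------------------------------------------------------------------
# Media and therapy candidates
# ---------------------------------------------------------------------------


@dataclass
class Medium:
    """Named set of maximal uptake rates on exchange reactions
    (mmol/gDW/h; uptake is the backward direction of an export exchange)."""

    name: str
    uptake_bounds: dict[str, float]

    def __post_init__(self) -> None:
        for rid, value in self.uptake_bounds.items():
            if value < 0:
                raise ValidationError(
                    f"medium {self.name!r}: uptake bound for {rid!r} must be >= 0"
                )


@dataclass(frozen=True)
class TargetModification:
    """A single intervention: knockout or upregulation of a gene set
    (a multi-gene set denotes an enzyme complex treated as one target)."""

    kind: str  # "knockout" | "upregulation"
    genes: frozenset[str]
    magnitude: Optional[float] = None  # fold-factor, upregulation only

    def __post_init__(self) -> None:
        if self.kind not in ("knockout", "upregulation"):
            raise ValidationError(f"unknown modification kind {self.kind!r}")
        if not self.genes:
            raise ValidationError("modification needs at least one gene")
        if self.kind == "knockout" and self.magnitude is not None:
            raise ValidationError("knockout carries no magnitude")
        if self.kind == "upregulation":
            if self.magnitude is None or self.magnitude <= 1:
                raise ValidationError("upregulation magnitude must be > 1")

    def label(self) -> str:
        sym = "KO" if self.kind == "knockout" else "UP"
        genes = "+".join(sorted(self.genes))
        if self.kind == "upregulation":
            return f"{sym}({genes})x{self.magnitude:g}"
        return f"{sym}({genes})"


@dataclass(frozen=True)
class TherapyCandidate:
    """An ordered set of up to two target modifications with disjoint genes."""

    modifications: tuple[TargetModification, ...] = ()

    def __post_init__(self) -> None:
        if len(self.modifications) > 2:
            raise ValidationError("therapy candidates hold at most two modifications")
        seen: set[str] = set()
        for mod in self.modifications:
            overlap = seen & mod.genes
            if overlap:
                raise ValidationError(
                    f"gene(s) {sorted(overlap)} appear in two modifications"
                )
            seen |= mod.genes

    @property
    def is_empty(self) -> bool:
        return not self.modifications

    def label(self) -> str:
        if self.is_empty:
            return "(none)"
        return " + ".join(m.label() for m in self.modifications)

    def key(self) -> tuple:
        """Canonical hashable key (order-insensitive) for memoization."""
        return tuple(
            sorted(
                (m.kind, tuple(sorted(m.genes)), m.magnitude)
                for m in self.modifications
            )
        )


# ---------------------------------------------------------------------------
# Medium / candidate application
# ---------------------------------------------------------------------------


def apply_medium(
    network: MetabolicNetwork,
    medium: Medium,
    secretion_cap: float = DEFAULT_SECRETION_CAP,
) -> MetabolicNetwork:
    """Return a copy of the network constrained to the given medium.

    Uptake (backward direction) of each listed exchange is capped at the
    medium value; uptake of every unlisted exchange is closed; secretion
    (forward direction) is open up to ``secretion_cap``.  Idempotent.
    """
    out = network.copy()
    exchange_ids = {r.id for r in out.exchanges}
    bad = set(medium.uptake_bounds) - exchange_ids
    if bad:
        raise ValidationError(
            f"medium {medium.name!r} lists non-exchange reaction(s): {sorted(bad)}"
        )
    for rxn in out.reactions:
        if not rxn.is_exchange:
            continue
        rxn.ub_f = secretion_cap
        rxn.lb_f = min(rxn.lb_f, secretion_cap)
        rxn.lb_b = 0.0
        rxn.ub_b = float(medium.uptake_bounds.get(rxn.id, 0.0))
    return out


def apply_candidate(
    network: MetabolicNetwork,
    candidate: TherapyCandidate,
    reference_flux: Optional[Mapping[str, float]] = None,
    flux_tol: float = 1e-9,
) -> MetabolicNetwork:
    """Return a copy of the network with a therapy candidate applied.

    Knockouts zero every reaction whose GPR rule becomes inactive.
    Upregulation enforces a minimum flux of ``magnitude x |reference net
    flux|`` (capped at the existing upper bound, in the reference flux's
    direction) on every still-active reaction whose GPR involves a target
    gene.  ``reference_flux`` maps reaction id -> net flux of the
    unperturbed cell and is required when any upregulation is present.
    """
    out = network.copy()
    if candidate.is_empty:
        return out

    knocked: set[str] = set()
    for mod in candidate.modifications:
        if mod.kind == "knockout":
            knocked |= mod.genes
    known = out.genes
    unknown = knocked - known
    if unknown:
        warnings.warn(
            f"knocked gene(s) not present in any GPR: {sorted(unknown)}", stacklevel=2
        )
    if knocked:
        for rxn in out.reactions:
            if rxn.gpr is not None and not rxn.gpr.is_active(frozenset(knocked)):
                rxn.knock_out()

    ups = [m for m in candidate.modifications if m.kind == "upregulation"]
    if ups:
        if reference_flux is None:
            raise ValidationError("upregulation requires a reference flux state")
        for mod in ups:
            touched = False
            for rxn in out.reactions:
                if rxn.gpr is None or not (rxn.gpr.genes & mod.genes):
                    continue
                if not rxn.gpr.is_active(frozenset(knocked)):
                    continue  # knocked out by the partner modification
                ref = float(reference_flux.get(rxn.id, 0.0))
                if abs(ref) <= flux_tol:
                    continue
                target = mod.magnitude * abs(ref)  # type: ignore[operand]
                if ref > 0:
                    rxn.lb_f = min(max(rxn.lb_f, target), rxn.ub_f)
                else:
                    rxn.lb_b = min(max(rxn.lb_b, target), rxn.ub_b)
                touched = True
            if not touched:
                warnings.warn(
                    f"upregulation {mod.label()} is a no-op: zero reference flux "
                    "on all affected reactions",
                    stacklevel=2,
                )
    return out


# ---------------------------------------------------------------------------
# SBML I/O via cobrapy
# ---------------------------------------------------------------------------

_ROLE_NOTE_KEY = "actd_role"


def to_cobra(network: MetabolicNetwork):
    """Convert to a cobra.Model (net-bound representation)."""
    import cobra

    model = cobra.Model(network.id)
    mets = {}
    for sp in network.species:
        met = cobra.Metabolite(
            sp.id, name=sp.name, compartment=sp.compartment, formula=sp.formula
        )
        mets[sp.id] = met
    model.add_metabolites(list(mets.values()))
    roles = network.objectives.roles()
    rxns = []
    for rxn in network.reactions:
        if rxn.lb_f > 0 and rxn.ub_b > 0:
            warnings.warn(
                f"reaction {rxn.id!r}: simultaneous forward lower bound and "
                "open backward direction cannot be expressed as net SBML "
                "bounds; writing the net range",
                stacklevel=2,
            )
        crx = cobra.Reaction(rxn.id, name=rxn.name)
        lb, ub = rxn.net_bounds
        rxns.append(crx)
        model.add_reactions([crx])
        crx.add_metabolites({mets[sid]: c for sid, c in rxn.stoichiometry.items()})
        crx.bounds = (lb, ub)
        if rxn.gpr is not None:
            crx.gene_reaction_rule = rxn.gpr.to_string()
        note_bits = []
        if rxn.id in roles:
            note_bits.append(roles[rxn.id])
        if rxn.is_exchange:
            note_bits.append("exchange")
        if note_bits:
            crx.notes[_ROLE_NOTE_KEY] = ";".join(note_bits)
    if network.objectives.biomass:
        model.objective = network.objectives.biomass
    # cobra collects genes from GPR sets; sort for byte-identical output
    model.genes.sort(key=lambda g: g.id)
    model.genes._generate_index()
    return model


def from_cobra(model) -> MetabolicNetwork:
    """Convert a cobra.Model to the split-flux representation."""
    species = []
    for met in model.metabolites:
        mass = None
        try:
            mass = met.formula_weight / 1000.0 if met.formula else None  # g/mmol
        except Exception:
            mass = None
        species.append(
            Species(
                id=met.id,
                name=met.name or "",
                compartment=met.compartment or "c",
                formula=met.formula or None,
                molar_mass=mass,
            )
        )
    reactions = []
    roles: dict[str, str] = {}
    for crx in model.reactions:
        lb_f, ub_f, lb_b, ub_b = split_bounds(crx.lower_bound, crx.upper_bound)
        note = str(crx.notes.get(_ROLE_NOTE_KEY, ""))
        note_bits = [b for b in note.split(";") if b]
        is_exchange = crx.boundary or "exchange" in note_bits
        for bit in note_bits:
            if bit != "exchange":
                roles[crx.id] = bit
        gpr = GprRule.from_string(crx.gene_reaction_rule)
        reactions.append(
            Reaction(
                id=crx.id,
                name=crx.name or "",
                stoichiometry={m.id: c for m, c in crx.metabolites.items()},
                lb_f=lb_f,
                ub_f=ub_f,
                lb_b=lb_b,
                ub_b=ub_b,
                gpr=gpr,
                is_exchange=is_exchange,
            )
        )
    objectives = ObjectiveRegistry.from_roles(roles)
    return MetabolicNetwork(
        species=species, reactions=reactions, objectives=objectives, id=model.id or "network"
    )


def read_sbml(path: str) -> MetabolicNetwork:
    """Read an SBML L3 (+fbc) file into a MetabolicNetwork."""
    from cobra.io import read_sbml_model

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = read_sbml_model(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse SBML file {path!r}: {exc}") from exc
    try:
        return from_cobra(model)
    except ValidationError:
        raise
    except Exception as exc:
        raise FormatError(f"invalid network in {path!r}: {exc}") from exc


def write_sbml(network: MetabolicNetwork, path: str) -> None:
    """Write the network as SBML L3 + fbc (net-bound representation)."""
    from cobra.io import write_sbml_model

    model = to_cobra(network)
    write_sbml_model(model, str(path))


# ---------------------------------------------------------------------------
# Tabular / JSON I/O
# ---------------------------------------------------------------------------


def read_medium_tsv(path: str, name: Optional[str] = None) -> Medium:
    """Read a medium from TSV with columns ``exchange_id, max_uptake``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "exchange_id" not in cols or "max_uptake" not in cols:
        raise FormatError(
            f"medium file {path!r} needs columns exchange_id, max_uptake"
        )
    bounds = dict(
        zip(df[cols["exchange_id"]].astype(str), df[cols["max_uptake"]].astype(float))
    )
    import os

    return Medium(name=name or os.path.splitext(os.path.basename(path))[0], uptake_bounds=bounds)


def write_medium_tsv(medium: Medium, path: str) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "exchange_id": list(medium.uptake_bounds),
            "max_uptake": list(medium.uptake_bounds.values()),
        }
    ).to_csv(path, sep="\t", index=False)


def candidate_from_dict(d: Mapping) -> TherapyCandidate:
    mods = []
    for md in d.get("modifications", []):
        mods.append(
            TargetModification(
                kind=md["kind"],
                genes=frozenset(md["genes"]),
                magnitude=md.get("magnitude"),
            )
        )
    return TherapyCandidate(modifications=tuple(mods))


def candidate_to_dict(candidate: TherapyCandidate) -> dict:
    return {
        "modifications": [
            {
                "kind": m.kind,
                "genes": sorted(m.genes),
                **({"magnitude": m.magnitude} if m.magnitude is not None else {}),
            }
            for m in candidate.modifications
        ]
    }


def read_candidates_json(path: str) -> list[TherapyCandidate]:
    import json

    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, Mapping):
        data = data.get("candidates", [])
    return [candidate_from_dict(d) for d in data]
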