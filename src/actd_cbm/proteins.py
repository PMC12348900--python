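"""Lumped protein turnover reactions from amino-acid sequences.

Genome-scale human reconstructions carry no explicit turnover chemistry for
individual proteins (cytokines such as TNF-alpha, IFN-gamma and IL-6, or
structural muscle proteins such as myosin, actin and titin).  This module
builds, per protein, a single lumped polymerization reaction

    sum_j S_Aj Aj  +  S_H2O H2O  +  S_ATP ATP
        ->  S_prot Protein  +  S_ADP ADP  +  S_Pi Pi  +  S_H+ H+

whose stoichiometric coefficients are expressed in mmol per gram of
protein, so that one unit of synthesis flux (mmol/gDW/h of the reaction)
turns over exactly one gram of protein per gDW per hour.  With ``n_Aj`` the
residue counts, ``B = n_tot - 1`` peptide bonds and ``k_ATP`` the ATP cost
per bond (4-4.3 for translation including amino-acid activation):

    M_prot = sum_j n_Aj M_Aj - B * M_H2O          (condensation)
    S_Aj   = 1000 n_Aj / M_prot
    S_ATP  = S_ADP = S_Pi = S_H+ = 1000 k_ATP B / M_prot
    S_H2O  = 1000 (k_ATP - 1) B / M_prot          (net water consumed)
    S_prot = 1000 / M_prot

The net-water term is what elemental balance dictates: each peptide bond
releases one condensation water while each of the ``k_ATP`` ATP hydrolyses
consumes one, leaving ``k_ATP - 1`` net waters consumed per bond.  A
matching hydrolytic degradation reaction (protein + B waters -> free amino
acids) closes the recycling loop; its products can optionally be routed to
a secreted degradation-product species instead of the cytosolic pools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from actd_cbm.core import (
    DEFAULT_SECRETION_CAP,
    MetabolicNetwork,
    Reaction,
    Species,
    ValidationError,
)

# Average (not monoisotopic) molecular masses of the free amino acids,
# g/mol.  Average masses are the right basis for per-gram stoichiometry of
# bulk protein.
AMINO_ACID_MASS: dict[str, float] = {
    "A": 89.09,
    "R": 174.20,
    "N": 132.12,
    "D": 133.10,
    "C": 121.16,
    "Q": 146.15,
    "E": 147.13,
    "G": 75.07,
    "H": 155.16,
    "I": 131.17,
    "L": 131.17,
    "K": 146.19,
    "M": 149.21,
    "F": 165.19,
    "P": 115.13,
    "S": 105.09,
    "T": 119.12,
    "W": 204.23,
    "Y": 181.19,
    "V": 117.15,
}

WATER_MASS = 18.015
# Average masses chosen to satisfy ATP + H2O -> ADP + Pi + H+ exactly.
ADP_MASS = 427.201
PI_MASS = 96.987  # hydrogenphosphate
HPLUS_MASS = 1.008
ATP_MASS = ADP_MASS + PI_MASS + HPLUS_MASS - WATER_MASS  # 507.181

#: one-letter code -> species id base (BiGG style); compartment suffix added.
AMINO_ACID_SPECIES: dict[str, str] = {
    "A": "ala__L",
    "R": "arg__L",
    "N": "asn__L",
    "D": "asp__L",
    "C": "cys__L",
    "Q": "gln__L",
    "E": "glu__L",
    "G": "gly",
    "H": "his__L",
    "I": "ile__L",
    "L": "leu__L",
    "K": "lys__L",
    "M": "met__L",
    "F": "phe__L",
    "P": "pro__L",
    "S": "ser__L",
    "T": "thr__L",
    "W": "trp__L",
    "Y": "tyr__L",
    "V": "val__L",
}

COFACTOR_SPECIES = {
    "atp": "atp",
    "adp": "adp",
    "pi": "pi",
    "h": "h",
    "h2o": "h2o",
}


@dataclass
class ProteinSpec:
    """A protein to lump into the network."""

    name: str
    sequence: str
    k_atp: float = 4.0  # ATP per peptide bond
    compartment: str = "c"
    secrete_degradation_products: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.strip().upper()
        if len(self.sequence) < 1:
            raise ValidationError(f"protein {self.name!r}: empty sequence")
        if self.k_atp < 1:
            # k_atp = 1 is the zero-net-water limit; below that synthesis
            # would have to emit water it never consumed
            raise ValidationError(f"protein {self.name!r}: k_atp must be >= 1")
        bad = [
            (i + 1, ch)
            for i, ch in enumerate(self.sequence)
            if ch not in AMINO_ACID_MASS
        ]
        if bad:
            pos = ", ".join(f"{ch!r} at position {i}" for i, ch in bad[:5])
            raise ValidationError(
                f"protein {self.name!r}: non-standard residue(s): {pos}"
            )


@dataclass
class LumpedCoefficients:
    """Stoichiometric coefficients of the lumped turnover reactions,
    mmol per gram of protein."""

    s_aa: dict[str, float]  # one-letter residue -> S_Aj
    s_h2o: float  # net water consumed by synthesis
    s_atp: float  # = S_ADP = S_Pi = S_H+
    s_protein: float
    m_protein: float  # g/mol
    n_bonds: int

    @property
    def s_adp(self) -> float:
        return self.s_atp

    @property
    def s_pi(self) -> float:
        return self.s_atp

    @property
    def s_hplus(self) -> float:
        return self.s_atp

    def mass_residual(self) -> float:
        """Per-gram mass imbalance of the synthesis reaction (should be ~0)."""
        lhs = (
            sum(AMINO_ACID_MASS[a] * s for a, s in self.s_aa.items())
            + self.s_h2o * WATER_MASS
            + self.s_atp * ATP_MASS
        )
        rhs = (
            self.s_protein * self.m_protein
            + self.s_atp * (ADP_MASS + PI_MASS + HPLUS_MASS)
        )
        return (lhs - rhs) / 1000.0  # grams per gram of protein


def compute_lumped_coefficients(spec: ProteinSpec) -> LumpedCoefficients:
    """Residue counts -> per-gram stoichiometry of the lumped reactions."""
    counts: dict[str, int] = {}
    for ch in spec.sequence:
        counts[ch] = counts.get(ch, 0) + 1
    n_tot = len(spec.sequence)
    bonds = n_tot - 1
    m_protein = sum(n * AMINO_ACID_MASS[a] for a, n in counts.items()) - bonds * WATER_MASS
    s_aa = {a: 1000.0 * n / m_protein for a, n in counts.items()}
    s_atp = 1000.0 * spec.k_atp * bonds / m_protein
    s_h2o = 1000.0 * (spec.k_atp - 1.0) * bonds / m_protein
    return LumpedCoefficients(
        s_aa=s_aa,
        s_h2o=s_h2o,
        s_atp=s_atp,
        s_protein=1000.0 / m_protein,
        m_protein=m_protein,
        n_bonds=bonds,
    )


@dataclass
class ProteinReactionSet:
    """Species and reactions generated for one protein."""

    species: list[Species] = field(default_factory=list)
    synthesis: Optional[Reaction] = None
    degradation: Optional[Reaction] = None
    extras: list[Reaction] = field(default_factory=list)  # export/exchange

    @property
    def reactions(self) -> list[Reaction]:
        out = [r for r in (self.synthesis, self.degradation) if r is not None]
        return out + list(self.extras)


def _species_id(base: str, compartment: str) -> str:
    return f"{base}_{compartment}"


def build_protein_reactions(
    spec: ProteinSpec,
    coeffs: Optional[LumpedCoefficients] = None,
    network: Optional[MetabolicNetwork] = None,
    extracellular_compartment: str = "e",
) -> ProteinReactionSet:
    """Build synthesis, degradation and recycling reactions for a protein.

    When ``network`` is given, cofactor and amino-acid species are required
    to exist in the protein's compartment (validation error otherwise);
    newly created species (the protein itself, optional secreted
    degradation products) are returned in the result.
    """
    coeffs = coeffs or compute_lumped_coefficients(spec)
    comp = spec.compartment
    known = set(network.species_ids) if network is not None else None

    def resolve(base: str, what: str) -> str:
        sid = _species_id(base, comp)
        if known is not None and sid not in known:
            raise ValidationError(
                f"protein {spec.name!r}: required {what} species {sid!r} "
                f"missing from compartment {comp!r}"
            )
        return sid

    atp = resolve(COFACTOR_SPECIES["atp"], "cofactor")
    adp = resolve(COFACTOR_SPECIES["adp"], "cofactor")
    pi = resolve(COFACTOR_SPECIES["pi"], "cofactor")
    h = resolve(COFACTOR_SPECIES["h"], "cofactor")
    h2o = resolve(COFACTOR_SPECIES["h2o"], "cofactor")
    aa_ids = {
        a: resolve(AMINO_ACID_SPECIES[a], "amino-acid") for a in coeffs.s_aa
    }

    result = ProteinReactionSet()
    prot_id = _species_id(f"protein_{spec.name}", comp)
    result.species.append(
        Species(
            id=prot_id,
            name=f"{spec.name} (lumped protein)",
            compartment=comp,
            molar_mass=coeffs.m_protein / 1000.0,
        )
    )

    synth_stoich: dict[str, float] = {aa_ids[a]: -s for a, s in coeffs.s_aa.items()}
    synth_stoich[h2o] = synth_stoich.get(h2o, 0.0) - coeffs.s_h2o
    synth_stoich[atp] = synth_stoich.get(atp, 0.0) - coeffs.s_atp
    synth_stoich[prot_id] = coeffs.s_protein
    synth_stoich[adp] = synth_stoich.get(adp, 0.0) + coeffs.s_adp
    synth_stoich[pi] = synth_stoich.get(pi, 0.0) + coeffs.s_pi
    synth_stoich[h] = synth_stoich.get(h, 0.0) + coeffs.s_hplus
    result.synthesis = Reaction(
        id=f"SYN_{spec.name}",
        name=f"{spec.name} synthesis (lumped)",
        stoichiometry={k: v for k, v in synth_stoich.items() if v != 0.0},
        lb_f=0.0,
        ub_f=DEFAULT_SECRETION_CAP,
    )

    # Hydrolytic degradation: protein + B waters -> free amino acids (the
    # recycling leg: products re-enter the same compartment's pools), or a
    # lumped secreted degradation-product species.
    deg_stoich: dict[str, float] = {
        prot_id: -coeffs.s_protein,
        h2o: -coeffs.n_bonds * coeffs.s_protein,
    }
    if spec.secrete_degradation_products:
        dp_id = _species_id(f"degprod_{spec.name}", extracellular_compartment)
        result.species.append(
            Species(
                id=dp_id,
                name=f"{spec.name} degradation products",
                compartment=extracellular_compartment,
            )
        )
        deg_stoich[dp_id] = sum(coeffs.s_aa.values())
        result.extras.append(
            Reaction(
                id=f"EX_degprod_{spec.name}",
                name=f"{spec.name} degradation product export",
                stoichiometry={dp_id: -1.0},
                is_exchange=True,
            )
        )
    else:
        for a, s in coeffs.s_aa.items():
            deg_stoich[aa_ids[a]] = deg_stoich.get(aa_ids[a], 0.0) + s
    result.degradation = Reaction(
        id=f"DEG_{spec.name}",
        name=f"{spec.name} degradation (lumped)",
        stoichiometry={k: v for k, v in deg_stoich.items() if v != 0.0},
    )
    return result


def extend_network(
    network: MetabolicNetwork,
    protein_specs: Sequence[ProteinSpec],
    extracellular_compartment: str = "e",
    on_collision: str = "error",
) -> MetabolicNetwork:
    """Insert lumped turnover reactions for each protein into a copy of the
    network and register the synthesis/degradation reactions as named
    objectives.  ``on_collision`` in {"error", "skip"} controls repeated
    extension with the same protein."""
    out = network.copy()
    for spec in protein_specs:
        if f"SYN_{spec.name}" in set(out.reaction_ids):
            if on_collision == "skip":
                warnings.warn(
                    f"protein {spec.name!r} already present; skipping", stacklevel=2
                )
                continue
            raise ValidationError(f"protein {spec.name!r} already in the network")
        built = build_protein_reactions(
            spec, network=out, extracellular_compartment=extracellular_compartment
        )
        existing = set(out.species_ids)
        for sp in built.species:
            if sp.id in existing:
                raise ValidationError(
                    f"species id collision while extending: {sp.id!r}"
                )
        out.species.extend(built.species)
        out.reactions.extend(built.reactions)
        out.objectives.protein_synthesis[spec.name] = built.synthesis.id
        out.objectives.protein_degradation[spec.name] = built.degradation.id
        out._validate()
    return out


def read_protein_specs_json(path: str, fasta_path: Optional[str] = None) -> list[ProteinSpec]:
    """Read protein specs from JSON; sequences inline or via a FASTA file
    referenced by ``fasta_id``."""
    import json

    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, Mapping):
        data = data.get("proteins", [])
    seqs: dict[str, str] = {}
    if fasta_path:
        seqs = read_fasta(fasta_path)
    specs = []
    for d in data:
        seq = d.get("sequence")
        if seq is None:
            fid = d.get("fasta_id")
            if fid is None or fid not in seqs:
                raise ValidationError(
                    f"protein {d.get('name')!r}: no sequence and no resolvable fasta_id"
                )
            seq = seqs[fid]
        specs.append(
            ProteinSpec(
                name=d["name"],
                sequence=seq,
                k_atp=float(d.get("k_atp", 4.0)),
                compartment=d.get("compartment", "c"),
                secrete_degradation_products=bool(
                    d.get("secrete_degradation_products", False)
                ),
            )
        )
    return specs


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
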