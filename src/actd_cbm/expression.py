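"""Transcriptomic confidence classes and weighted-flux weights.

Gene expression (one condition) is split by quartiles into four confidence
classes, propagated through GPR rules (complex = minimum of subunits,
isozymes = maximum), and mapped to the weight vector of the weighted
total-flux minimization:

    high   -> 1/4        (level >= Q3)
    medium -> 1/2        (Q2 <= level < Q3)
    negative -> 3/4      (level < Q1)
    none   -> 1          ([Q1, Q2) or no usable gene information)

Low weight lets well-supported reactions carry flux cheaply, biasing the
parsimonious solution toward transcriptionally supported routes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from actd_cbm.core import GprRule, MetabolicNetwork, ValidationError

#: confidence class -> UFD weight
CLASS_WEIGHTS: dict[str, float] = {
    "high": 0.25,
    "medium": 0.5,
    "negative": 0.75,
    "none": 1.0,
}

#: ordering used for GPR propagation (min over AND, max over OR);
#: "none" is excluded from the min/max unless every child is "none".
_CLASS_RANK = {"negative": 0, "medium": 1, "high": 2}


@dataclass
class ExpressionProfile:
    """Expression levels (arbitrary units, >= 0) for one condition."""

    values: dict[str, float]
    condition: str = ""

    def __post_init__(self) -> None:
        if len(self.values) < 4:
            raise ValidationError("expression profile needs >= 4 genes for quartiles")
        for gene, level in self.values.items():
            if level < 0:
                raise ValidationError(f"negative expression for gene {gene!r}")


@dataclass
class ConfidenceAssignment:
    """Per-reaction confidence class and UFD weight."""

    classes: dict[str, str] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)

    def weight_vector(self, network: MetabolicNetwork) -> np.ndarray:
        return np.array([self.weights.get(r.id, 1.0) for r in network.reactions])

    def to_frame(self) -> pd.DataFrame:
        rids = sorted(self.classes)
        return pd.DataFrame(
            {
                "reaction_id": rids,
                "class": [self.classes[r] for r in rids],
                "weight": [self.weights[r] for r in rids],
            }
        )


def classify_genes(profile: ExpressionProfile) -> dict[str, str]:
    """Quartile-based gene classification.

    Quartiles are linear-interpolation sample quantiles over all genes in
    the profile.  Fully degenerate profiles (Q1 == Q3) carry no rank
    information and classify every gene as "none".
    """
    if not profile.values:
        raise ValidationError("empty expression profile")
    levels = np.array(list(profile.values.values()), dtype=float)
    q1, q2, q3 = np.quantile(levels, [0.25, 0.5, 0.75])
    out: dict[str, str] = {}
    degenerate = q3 <= q1
    for gene, level in profile.values.items():
        if degenerate:
            out[gene] = "none"
        elif level >= q3:
            out[gene] = "high"
        elif q2 <= level:
            out[gene] = "medium"
        elif level < q1:
            out[gene] = "negative"
        else:
            out[gene] = "none"
    return out


def propagate_gpr_class(rule: Optional[GprRule], gene_classes: Mapping[str, str]) -> str:
    """Propagate gene confidence classes through a GPR rule.

    AND -> minimum confidence of children, OR -> maximum, over the order
    negative < medium < high; children of class "none" are excluded unless
    all children are "none" (then the node is "none").  Missing genes are
    treated as "none".
    """
    if rule is None:
        return "none"
    if rule.op == "gene":
        return gene_classes.get(rule.gene, "none")
    child_classes = [propagate_gpr_class(c, gene_classes) for c in rule.children]
    informative = [c for c in child_classes if c != "none"]
    if not informative:
        return "none"
    if rule.op == "and":
        return min(informative, key=_CLASS_RANK.__getitem__)
    return max(informative, key=_CLASS_RANK.__getitem__)


def reaction_confidence(
    network: MetabolicNetwork, gene_classes: Mapping[str, str]
) -> ConfidenceAssignment:
    """Reaction-level confidence classes and UFD weights for a network."""
    missing = network.genes - set(gene_classes)
    if missing:
        warnings.warn(
            f"{len(missing)} GPR gene(s) missing from the expression profile; "
            "treated as class 'none'",
            stacklevel=2,
        )
    assignment = ConfidenceAssignment()
    for rxn in network.reactions:
        cls = propagate_gpr_class(rxn.gpr, gene_classes)
        assignment.classes[rxn.id] = cls
        assignment.weights[rxn.id] = CLASS_WEIGHTS[cls]
    return assignment


def read_expression_tsv(path: str, condition: Optional[str] = None) -> ExpressionProfile:
    """Read an expression table (columns ``gene_id, value[, condition]``)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "gene_id" not in cols or "value" not in cols:
        raise ValidationError(
            f"expression file {path!r} needs columns gene_id, value"
        )
    if condition is not None and "condition" in cols:
        df = df[df[cols["condition"]].astype(str) == condition]
    label = condition or (
        str(df[cols["condition"]].iloc[0]) if "condition" in cols and len(df) else ""
    )
    return ExpressionProfile(
        values=dict(zip(df[cols["gene_id"]].astype(str), df[cols["value"]].astype(float))),
        condition=label,
    )


def write_expression_tsv(profiles: list[ExpressionProfile], path: str) -> None:
    rows = []
    for prof in profiles:
        for gene in sorted(prof.values):
            rows.append((gene, prof.values[gene], prof.condition))
    pd.DataFrame(rows, columns=["gene_id", "value", "condition"]).to_csv(
        path, sep="\t", index=False
    )
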