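"""Differential metabolite-flow classification and medium-independent
biomarker selection.

Disease and healthy flow profiles over the same sigma grid are compared
per metabolite and medium.  Significance is assessed with a two-sided
Wilcoxon rank-sum test on the two flow series (alpha = 0.05 by default,
raw p-values).  Significant changes are classified from the two envelopes
D = [d-, d+] and H = [h-, h+] by interval algebra:

    CI  complete increase   disease envelope entirely above healthy
    CD  complete decrease   entirely below
    PI  partial increase    overlapping, both endpoints shifted up
    PD  partial decrease    overlapping, both endpoints shifted down
    II  inclusive increase  one envelope contains the other, median up
    ID  inclusive decrease  containment, median down
    NS  not significant

A metabolite is a *medium-independent* biomarker when its class is CI in
every medium of the panel, or CD in every medium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from actd_cbm.core import ValidationError
from actd_cbm.pmfva import FlowProfile

CLASSES = ("CI", "PI", "II", "ID", "PD", "CD")
DEFAULT_ALPHA = 0.05


@dataclass
class BiomarkerCall:
    """Classification of one metabolite's flow change in one medium."""

    metabolite_id: str
    medium: str
    cls: str
    p_value: float
    disease_envelope: tuple[float, float]
    healthy_envelope: tuple[float, float]

    @property
    def significant(self) -> bool:
        return self.cls != "NS"


@dataclass
class MediumPanelResult:
    """Per-medium calls for one metabolite plus the medium-independence flag."""

    metabolite_id: str
    calls: dict[str, BiomarkerCall] = field(default_factory=dict)
    medium_independent: bool = False
    direction: Optional[str] = None  # "increase" | "decrease"


def classify_envelopes(
    d_lo: float,
    d_hi: float,
    h_lo: float,
    h_hi: float,
    d_center: float,
    h_center: float,
) -> str:
    """Interval-algebra classification of a significant flow change.

    ``d_center``/``h_center`` break containment cases (medians of the two
    series; equal centers fall back to NS upstream)."""
    if d_lo >= h_hi and d_lo + d_hi > h_lo + h_hi:
        return "CI"
    if d_hi <= h_lo and d_lo + d_hi < h_lo + h_hi:
        return "CD"
    contains = (d_lo <= h_lo and d_hi >= h_hi) or (h_lo <= d_lo and h_hi >= d_hi)
    if contains:
        if d_center > h_center:
            return "II"
        if d_center < h_center:
            return "ID"
        return "NS"
    if d_lo >= h_lo and d_hi >= h_hi:
        return "PI"
    if d_lo <= h_lo and d_hi <= h_hi:
        return "PD"
    return "NS"  # unreachable for real intervals


def compare_flows(
    disease: FlowProfile,
    healthy: FlowProfile,
    alpha: float = DEFAULT_ALPHA,
    medium: str = "",
) -> BiomarkerCall:
    """Classify the disease-vs-healthy flow change of one metabolite."""
    if disease.sigma.shape != healthy.sigma.shape or not np.allclose(
        disease.sigma, healthy.sigma
    ):
        raise ValidationError("flow profiles are on different sigma grids")
    d_vals = disease.feasible_flows
    h_vals = healthy.feasible_flows
    if d_vals.size == 0 or h_vals.size == 0:
        raise ValidationError("cannot compare profiles with no feasible points")

    if d_vals.size == h_vals.size and np.allclose(d_vals, h_vals):
        p = 1.0
    else:
        p = float(stats.ranksums(d_vals, h_vals).pvalue)

    cls = "NS"
    if p < alpha:
        d_med, h_med = float(np.median(d_vals)), float(np.median(h_vals))
        if d_med == h_med:
            d_med, h_med = float(np.mean(d_vals)), float(np.mean(h_vals))
        if d_med == h_med:
            cls = "NS"
        else:
            cls = classify_envelopes(
                disease.r_min, disease.r_max, healthy.r_min, healthy.r_max,
                d_med, h_med,
            )
    return BiomarkerCall(
        metabolite_id=disease.metabolite_id,
        medium=medium,
        cls=cls,
        p_value=p,
        disease_envelope=disease.envelope,
        healthy_envelope=healthy.envelope,
    )


BiomarkerPanel = dict[str, dict[str, BiomarkerCall]]  # metabolite -> medium -> call


def build_panel(
    disease_profiles: Mapping[str, Mapping[str, FlowProfile]],
    healthy_profiles: Mapping[str, Mapping[str, FlowProfile]],
    alpha: float = DEFAULT_ALPHA,
) -> BiomarkerPanel:
    """Compare flows across a media panel.

    Both arguments map medium name -> metabolite id -> FlowProfile; the
    media and metabolite sets must coincide."""
    media = sorted(disease_profiles)
    if sorted(healthy_profiles) != media:
        raise ValidationError("disease and healthy panels cover different media")
    panel: BiomarkerPanel = {}
    for medium in media:
        dprofs, hprofs = disease_profiles[medium], healthy_profiles[medium]
        for mid in dprofs:
            if mid not in hprofs:
                raise ValidationError(
                    f"metabolite {mid!r} missing from healthy panel in {medium!r}"
                )
            call = compare_flows(dprofs[mid], hprofs[mid], alpha=alpha, medium=medium)
            panel.setdefault(mid, {})[medium] = call
    return panel


def medium_independent(panel: BiomarkerPanel) -> dict[str, MediumPanelResult]:
    """Flag metabolites that are CI in every medium or CD in every medium."""
    out: dict[str, MediumPanelResult] = {}
    for mid, calls in panel.items():
        if len(calls) < 2:
            raise ValidationError(
                f"metabolite {mid!r}: medium-independence needs >= 2 media"
            )
        classes = {c.cls for c in calls.values()}
        res = MediumPanelResult(metabolite_id=mid, calls=dict(calls))
        if classes == {"CI"}:
            res.medium_independent, res.direction = True, "increase"
        elif classes == {"CD"}:
            res.medium_independent, res.direction = True, "decrease"
        out[mid] = res
    return out


def tabulate_classes(panel: BiomarkerPanel) -> pd.DataFrame:
    """Per-medium counts of each significant class (plus the row total)."""
    media = sorted({m for calls in panel.values() for m in calls})
    counts = {m: {c: 0 for c in CLASSES} for m in media}
    for calls in panel.values():
        for medium, call in calls.items():
            if call.cls in CLASSES:
                counts[medium][call.cls] += 1
    df = pd.DataFrame.from_dict(counts, orient="index").reindex(columns=list(CLASSES))
    if df.empty:
        df = pd.DataFrame(columns=list(CLASSES))
    df["Total"] = df.sum(axis=1)
    df.index.name = "medium"
    return df


def panel_to_frame(panel: BiomarkerPanel) -> pd.DataFrame:
    rows = []
    for mid in sorted(panel):
        for medium in sorted(panel[mid]):
            call = panel[mid][medium]
            rows.append(
                (
                    mid,
                    medium,
                    call.cls,
                    call.p_value,
                    *call.disease_envelope,
                    *call.healthy_envelope,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "metabolite_id",
            "medium",
            "class",
            "p_value",
            "d_min",
            "d_max",
            "h_min",
            "h_max",
        ],
    )
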