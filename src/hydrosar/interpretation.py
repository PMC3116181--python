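"""Variable importance (VIP), coefficient signs, and the strong/weak
contributor classification.

VIP for variable j over A components, with unit-norm weights w_a and
SSY_a = c_a²·t_aᵀt_a the response sum of squares explained by component a:

    VIP_j = sqrt( p · Σ_a SSY_a w_ja² / Σ_a SSY_a )

so the squared VIPs average to 1 over the p variables. Classification:
VIP > 1.0 → strong contributor; 0.5 ≤ VIP ≤ 1.0 → weak; VIP < 0.5 →
unimportant (exact boundary values fall in the weaker class). The sign of
a contributor is the sign of its regression coefficient on the
scaled/centered data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls import PLSRegressionNIPALS

VIP_STRONG = 1.0
VIP_WEAK = 0.5


def vip(model: PLSRegressionNIPALS) -> np.ndarray:
    """Per-variable Variable Importance for the Projection."""
    W = model.x_weights_
    T = model.x_scores_
    c = model.y_loadings_
    p = W.shape[0]
    ssy = c ** 2 * np.einsum("ia,ia->a", T, T)
    total = ssy.sum()
    if total <= 0:
        return np.zeros(p)
    return np.sqrt(p * (W ** 2 @ ssy) / total)


@dataclass
class ContributionRecord:
    variable: str
    vip: float
    coefficient: float
    importance: str  # strong | weak | unimportant
    sign: str        # positive | negative | none


@dataclass
class ContributionReport:
    activity: str
    x_set: str
    records: list[ContributionRecord] = field(default_factory=list)

    def by_class(self, importance: str, sign: str) -> list[ContributionRecord]:
        """Records of one (importance, sign) cell, descending VIP; ties
        keep the fixed descriptor column order."""
        picked = [r for r in self.records
                  if r.importance == importance and r.sign == sign]
        return sorted(picked, key=lambda r: -r.vip)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.variable, r.vip, r.coefficient, r.importance, r.sign)
             for r in self.records],
            columns=["variable", "vip", "coefficient", "importance", "sign"],
        )


def _classify_one(v: float) -> str:
    if v > VIP_STRONG:
        return "strong"
    if v >= VIP_WEAK:
        return "weak"
    return "unimportant"


def classify_contributors(
    vip_values,
    coefficients,
    labels=None,
    activity: str = "",
    x_set: str = "",
) -> ContributionReport:
    """Assign every descriptor an (importance, sign) class from its VIP
    and coefficient. Pure function of its inputs: idempotent and
    order-independent."""
    if isinstance(coefficients, pd.Series):
        if labels is None:
            labels = list(coefficients.index)
        coefficients = coefficients.to_numpy()
    v = np.asarray(vip_values, dtype=float).ravel()
    b = np.asarray(coefficients, dtype=float).ravel()
    if len(v) != len(b):
        raise ValueError(f"{len(v)} VIP values but {len(b)} coefficients")
    if labels is None:
        labels = [f"x{j}" for j in range(len(v))]
    if len(labels) != len(v):
        raise ValueError(f"{len(labels)} labels for {len(v)} variables")
    records = [
        ContributionRecord(
            variable=str(lab),
            vip=float(vj),
            coefficient=float(bj),
            importance=_classify_one(float(vj)),
            sign="none" if bj == 0 else ("positive" if bj > 0 else "negative"),
        )
        for lab, vj, bj in zip(labels, v, b)
    ]
    return ContributionReport(activity=activity, x_set=x_set, records=records)


def interpret_model(
    model: PLSRegressionNIPALS, activity: str = "", x_set: str = ""
) -> ContributionReport:
    """VIP + coefficient classification of a fitted model in one call."""
    from .pls import coefficients as coef_of

    b = coef_of(model)
    labels = list(b.index) if isinstance(b, pd.Series) else None
    return classify_contributors(vip(model), b, labels=labels,
                                 activity=activity, x_set=x_set)


def _render_cell(strong: list[ContributionRecord],
                 weak: list[ContributionRecord]) -> str:
    """Strong contributors first, weak ones bracketed — mirroring the
    bold/bracket convention of printed contributor summaries."""
    parts = [r.variable for r in strong]
    text = ", ".join(parts)
    if weak:
        text += (" " if text else "") + "(" + ", ".join(r.variable for r in weak) + ")"
    return text


def contribution_table(reports: list[ContributionReport]) -> pd.DataFrame:
    """Cross-activity summary: one row per activity with rendered
    positive- and negative-contributor cells, plus the per-class lists."""
    rows = []
    for rep in reports:
        sp = rep.by_class("strong", "positive")
        wp = rep.by_class("weak", "positive")
        sn = rep.by_class("strong", "negative")
        wn = rep.by_class("weak", "negative")
        rows.append({
            "activity": rep.activity,
            "x_set": rep.x_set,
            "positive_contributors": _render_cell(sp, wp),
            "negative_contributors": _render_cell(sn, wn),
            "strong_positive": [r.variable for r in sp],
            "weak_positive": [r.variable for r in wp],
            "strong_negative": [r.variable for r in sn],
            "weak_negative": [r.variable for r in wn],
        })
    return pd.DataFrame(
        rows,
        columns=["activity", "x_set", "positive_contributors",
                 "negative_contributors", "strong_positive", "weak_positive",
                 "strong_negative", "weak_negative"],
    )
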