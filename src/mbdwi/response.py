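"""Treatment-response classification from longitudinal tumor diameters.

Response categories follow the diameter-based rules used for solid
tumors: complete response (CR) when the lesion disappears at any visit
within 12 months of the start of treatment; otherwise the 12-month
diameter decides — partial response (PR) for a decrease of more than 30%
from baseline, progressive disease (PD) for an increase of at least 20%,
stable disease (SD) in between.  CR/PR form the responder group, SD/PD
the non-responders.

Patients without an assessable measurement at or before 12 months are
excluded (raising :class:`ExcludedPatient`), mirroring study exclusion of
patients who progressed early or did not complete treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "DiameterSeries",
    "ResponseLabel",
    "ExcludedPatient",
    "classify_response",
    "nearest_assessment",
    "classify_table",
    "CATEGORY_TO_GROUP",
]

ASSESSMENT_MONTHS = 12.0
PR_SHRINKAGE = 0.30  # strict: decrease must exceed 30%
PD_GROWTH = 0.20     # inclusive: increase of at least 20%
FOLLOW_UP_LIMIT_MONTHS = 18.0

CATEGORY_TO_GROUP = {
    "CR": "responder",
    "PR": "responder",
    "SD": "non-responder",
    "PD": "non-responder",
}


class ExcludedPatient(ValueError):
    """Patient has no assessable measurement and is excluded upstream."""


@dataclass(frozen=True)
class DiameterSeries:
    """Largest axial tumor diameter at baseline and at follow-up visits.

    followups are (months_since_start, diameter_mm) pairs, strictly
    increasing in time, within the 18-month follow-up window.
    """

    patient_id: str
    baseline_mm: float
    followups: tuple

    def __post_init__(self):
        if not self.baseline_mm > 0:
            raise ValueError("baseline diameter must be > 0")
        fu = tuple((float(m), float(d)) for m, d in self.followups)
        months = [m for m, _ in fu]
        if any(m2 <= m1 for m1, m2 in zip(months, months[1:])):
            raise ValueError("follow-up times must be strictly increasing")
        if any(not 0 < m <= FOLLOW_UP_LIMIT_MONTHS for m in months):
            raise ValueError("follow-up times must lie in (0, 18] months")
        if any(d < 0 for _, d in fu):
            raise ValueError("diameters must be >= 0")
        object.__setattr__(self, "followups", fu)


@dataclass(frozen=True)
class ResponseLabel:
    category: str  # CR | PR | SD | PD
    group: str     # responder | non-responder
    decided_at_months: float


def nearest_assessment(series: DiameterSeries, target_months: float) -> tuple[float, float]:
    """The follow-up visit closest in time to ``target_months``.

    Ties are broken toward the earlier visit.
    """
    if not series.followups:
        raise ValueError("no follow-up visits")
    return min(series.followups, key=lambda v: (abs(v[0] - target_months), v[0]))


def classify_response(series: DiameterSeries, cr_epsilon_mm: float = 0.0) -> ResponseLabel:
    """Classify a diameter series into CR/PR/SD/PD and responder group.

    ``cr_epsilon_mm`` guards complete-response detection against
    measurement noise in simulated series (a diameter ≤ epsilon counts as
    disappearance); the default 0 requires an exact zero.
    """
    for months, diameter in series.followups:
        if months <= ASSESSMENT_MONTHS and diameter <= cr_epsilon_mm:
            return ResponseLabel("CR", "responder", months)

    assessable = [v for v in series.followups if v[0] <= ASSESSMENT_MONTHS]
    if not assessable:
        raise ExcludedPatient(
            f"patient {series.patient_id}: no measurement at or before "
            f"{ASSESSMENT_MONTHS:g} months"
        )
    months, d12 = nearest_assessment(series, ASSESSMENT_MONTHS)
    change = (d12 - series.baseline_mm) / series.baseline_mm
    if -change > PR_SHRINKAGE:
        category = "PR"
    elif change >= PD_GROWTH:
        category = "PD"
    else:
        category = "SD"
    return ResponseLabel(category, CATEGORY_TO_GROUP[category], months)


def classify_table(diameters: pd.DataFrame, cr_epsilon_mm: float = 0.0) -> pd.DataFrame:
    """Classify every patient in a long-format diameter table.

    ``diameters`` has columns patient_id, months, diameter_mm; the
    baseline is the row with months == 0.  Returns a table with columns
    patient_id, category, group, decided_at_months; excluded patients get
    category "excluded" and an empty group.
    """
    rows = []
    for pid, g in diameters.groupby("patient_id", sort=True):
        base = g.loc[g["months"] == 0, "diameter_mm"]
        if base.empty:
            raise ValueError(f"patient {pid}: missing baseline (months == 0) row")
        fu = g[g["months"] > 0].sort_values("months")
        series = DiameterSeries(str(pid), float(base.iloc[0]),
                                tuple(zip(fu["months"], fu["diameter_mm"])))
        try:
            lab = classify_response(series, cr_epsilon_mm)
            rows.append((str(pid), lab.category, lab.group, lab.decided_at_months))
        except ExcludedPatient:
            rows.append((str(pid), "excluded", "", float("nan")))
    return pd.DataFrame(rows, columns=["patient_id", "category", "group", "decided_at_months"])
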