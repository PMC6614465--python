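"""Diagnostic-stability curves over the months following schizophrenia onset.

Visits after the onset visit are binned into fixed 30-day months. Months
without a diagnosed visit inherit the previous month's labels (last
observation carried forward), so every patient contributes a label list to
every month of the horizon. Each month's pooled labels are normalised into a
probability distribution: the mass on F20 is the probability of maintaining
the diagnosis, mass elsewhere the probability of each alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import pandas as pd

from .cohort_selection import Cohort
from .registry_model import CodeTaxonomy, F2_DETAIL, VisitRecord

__all__ = [
    "SHIFT_DETAIL",
    "StabilityCurve",
    "month_index",
    "bin_and_fill",
    "stability_curve",
    "mean_share",
    "modal_label_fraction",
]

#: Rendering granularity for post-onset shift labels: the psychotic-spectrum
#: categories plus the mood and personality categories reported as the most
#: frequent alternative diagnoses (F31 bipolar, F34 persistent mood,
#: F60 specific personality disorder).
SHIFT_DETAIL: frozenset[str] = F2_DETAIL | {"F31", "F34", "F60"}


def month_index(onset_date: date, visit_date: date) -> int:
    """30-day month bin of a visit: month m covers days (30*(m-1), 30*m]
    after onset; the onset day itself is month 0."""
    days = (visit_date - onset_date).days
    if days < 0:
        raise ValueError(f"visit {visit_date} precedes onset {onset_date}")
    return -(-days // 30)  # ceil(days/30); 0 days -> month 0


def bin_and_fill(
    post_visits: list[VisitRecord],
    horizon: int = 48,
    taxonomy: CodeTaxonomy | None = None,
    censor_after_last_visit: bool = False,
) -> dict[int, list[str]]:
    """Per-month label lists for one patient, with carry-forward filling.

    ``post_visits[0]`` is the onset visit and seeds month 0. Months with at
    least one diagnosed visit receive every rendered label of those visits
    (both codes of a two-code visit). Empty months inherit the previous
    month's labels. With ``censor_after_last_visit`` the fill stops at the
    month of the last observed visit instead of running to the horizon.
    """
    if not post_visits:
        raise ValueError("patient has no onset visit")
    taxonomy = taxonomy or CodeTaxonomy(detail=SHIFT_DETAIL)
    onset_date = post_visits[0].visit_date

    observed: dict[int, list[str]] = {}
    for v in post_visits:
        if not v.has_diagnosis:
            continue
        m = month_index(onset_date, v.visit_date)
        if m > horizon:
            continue
        observed.setdefault(m, []).extend(taxonomy.render_visit(v))

    last_month = max(observed) if censor_after_last_visit else horizon
    filled: dict[int, list[str]] = {}
    previous = observed.get(0, [])
    for m in range(1, min(last_month, horizon) + 1):
        labels = observed.get(m)
        if labels:
            filled[m] = list(labels)
            previous = labels
        else:
            filled[m] = list(previous)
    return filled


@dataclass
class StabilityCurve:
    """Per-month probability distribution over diagnosis labels after onset."""

    horizon: int
    distributions: dict[int, dict[str, float]]  # month -> label -> probability
    label_counts: dict[int, dict[str, int]] = field(default_factory=dict)

    def probability(self, month: int, label: str) -> float:
        return self.distributions.get(month, {}).get(label, 0.0)

    @property
    def labels(self) -> list[str]:
        out: set[str] = set()
        for dist in self.distributions.values():
            out |= set(dist)
        return sorted(out)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (month, label, probability, n_labels)."""
        rows = []
        for m in sorted(self.distributions):
            total = sum(self.label_counts.get(m, {}).values())
            for lab, p in sorted(self.distributions[m].items()):
                rows.append({"month": m, "label": lab, "probability": p, "n_labels": total})
        return pd.DataFrame(rows, columns=["month", "label", "probability", "n_labels"])


def stability_curve(
    cohort: Cohort,
    horizon: int = 48,
    taxonomy: CodeTaxonomy | None = None,
    censor_after_last_visit: bool = False,
) -> StabilityCurve:
    """Pool every patient's filled monthly labels and normalise per month."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    taxonomy = taxonomy or CodeTaxonomy(detail=SHIFT_DETAIL)
    counts: dict[int, dict[str, int]] = {m: {} for m in range(1, horizon + 1)}
    for traj, onset in cohort:
        filled = bin_and_fill(
            traj.visits[onset:], horizon, taxonomy, censor_after_last_visit
        )
        for m, labels in filled.items():
            month_counts = counts[m]
            for lab in labels:
                month_counts[lab] = month_counts.get(lab, 0) + 1
    distributions: dict[int, dict[str, float]] = {}
    for m in range(1, horizon + 1):
        total = sum(counts[m].values())
        if total:
            distributions[m] = {lab: c / total for lab, c in counts[m].items()}
        else:
            distributions[m] = {}
    return StabilityCurve(horizon=horizon, distributions=distributions, label_counts=counts)


def mean_share(curve: StabilityCurve, label: str, months: range | None = None) -> float:
    """Average percentage of the label over months 1..horizon.

    A label never observed averages to 0.0.
    """
    months = months if months is not None else range(1, curve.horizon + 1)
    values = [curve.probability(m, label) * 100.0 for m in months]
    if not values:
        raise ValueError("no months requested")
    return sum(values) / len(values)


def modal_label_fraction(
    cohort: Cohort,
    label: str = "F20",
    horizon: int = 48,
    taxonomy: CodeTaxonomy | None = None,
) -> float:
    """Fraction of patients whose modal filled post-onset label is ``label``.

    A patient-level reading of prospective consistency, complementing the
    month-averaged curve share.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    taxonomy = taxonomy or CodeTaxonomy(detail=SHIFT_DETAIL)
    n_modal = 0
    for traj, onset in cohort:
        filled = bin_and_fill(traj.visits[onset:], horizon, taxonomy)
        pooled: dict[str, int] = {}
        for labels in filled.values():
            for lab in labels:
                pooled[lab] = pooled.get(lab, 0) + 1
        if pooled:
            top = max(pooled.items(), key=lambda kv: (kv[1], kv[0] == label))
            if top[0] == label:
                n_modal += 1
    return n_modal / len(cohort)
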