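"""Frequency tables of diagnoses before schizophrenia onset.

Three counting levels are supported:

* ``patient_first_visit`` — the diagnoses recorded at each patient's first
  ever visit (one table row per rendered label; a two-code visit contributes
  both labels). Denominator: number of patients.
* ``per_visit`` — every pre-onset visit counts once; a visit with two codes
  in different chapters counts under a chapter-pair combination row
  ("F3-F6"). Denominator: pre-onset visits with at least one diagnosis.
* ``patient_any`` — the fraction of patients who received the label at least
  once before onset, with combination codes expanded into both chapters
  (comorbidity counting).

Percentages are stored as exact count/denominator pairs and rounded half-up
to one decimal only at render time.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .cohort_selection import Cohort, split_pre_post
from .registry_model import CodeTaxonomy, VisitRecord, chapters_of, category_of

__all__ = [
    "FrequencyTable",
    "render_percentage",
    "initial_assessment_table",
    "pre_onset_visit_table",
    "patient_level_category_rates",
    "prior_diagnosis_fraction",
    "mean_prior_visits",
]


def render_percentage(count: int, denominator: int) -> float:
    """100*count/denominator rounded half-up to 1 decimal (table rendering rule)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(100 * count) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class FrequencyTable:
    """Counts and rendered percentages of diagnosis labels at a stated level."""

    level: str  # patient_first_visit | per_visit | patient_any
    rows: list[tuple[str, int]]  # (label, count), sorted by descending count
    denominator: int

    def __post_init__(self) -> None:
        if any(c < 0 for _, c in self.rows):
            raise ValueError("counts must be non-negative")
        self.rows = sorted(self.rows, key=lambda r: (-r[1], r[0]))

    def percentage(self, label: str) -> float:
        for lab, count in self.rows:
            if lab == label:
                return render_percentage(count, self.denominator)
        return 0.0

    def count(self, label: str) -> int:
        for lab, count in self.rows:
            if lab == label:
                return count
        return 0

    def filtered(self, min_count: int) -> "FrequencyTable":
        return FrequencyTable(
            level=self.level,
            rows=[r for r in self.rows if r[1] >= min_count],
            denominator=self.denominator,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": lab,
                    "count": count,
                    "percentage": render_percentage(count, self.denominator),
                }
                for lab, count in self.rows
            ],
            columns=["label", "count", "percentage"],
        )


def _combination_or_labels(visit: VisitRecord, taxonomy: CodeTaxonomy) -> list[str]:
    """Per-visit labels: a chapter-pair combination row when the two codes sit
    in different chapters, otherwise the rendered label(s)."""
    labels = taxonomy.render_visit(visit)
    if len(visit.codes) == 2 and not any(c.is_combination for c in visit.codes):
        ch = sorted(chapters_of(visit.codes[0]) | chapters_of(visit.codes[1]))
        if len(ch) == 2:
            return [f"{ch[0]}-{ch[1]}"]
        if len(labels) == 2 and labels[0] == labels[1]:
            return [labels[0]]
    return labels


def initial_assessment_table(
    cohort: Cohort, taxonomy: CodeTaxonomy | None = None, min_count: int = 1
) -> FrequencyTable:
    """Diagnoses at each patient's first registered visit.

    Every code of the first visit contributes one count of its rendered label
    (psychotic-spectrum categories at 3-character level, other chapters
    collapsed). Denominator: number of cohort patients.
    """
    taxonomy = taxonomy or CodeTaxonomy()
    counts: Counter[str] = Counter()
    for traj, _onset in cohort:
        counts.update(taxonomy.render_visit(traj.visits[0]))
    table = FrequencyTable(
        level="patient_first_visit", rows=list(counts.items()), denominator=len(cohort)
    )
    return table.filtered(min_count)


def pre_onset_visit_table(
    cohort: Cohort, taxonomy: CodeTaxonomy | None = None, min_count: int = 1
) -> FrequencyTable:
    """Per-visit diagnosis frequencies over all visits before onset.

    Two-code visits spanning different chapters count under a combination row.
    Denominator: total diagnosed pre-onset visits (undiagnosed visits carry no
    diagnosis and are excluded).
    """
    taxonomy = taxonomy or CodeTaxonomy()
    counts: Counter[str] = Counter()
    denominator = 0
    for traj, onset in cohort:
        pre, _post = split_pre_post(traj, onset)
        for visit in pre:
            if not visit.has_diagnosis:
                continue
            denominator += 1
            counts.update(_combination_or_labels(visit, taxonomy))
    table = FrequencyTable(
        level="per_visit", rows=list(counts.items()), denominator=max(denominator, 1)
    )
    return table.filtered(min_count)


def _patient_pre_onset_labels(visits: list[VisitRecord], taxonomy: CodeTaxonomy) -> set[str]:
    """Chapters plus 3-character categories a patient received before onset;
    combination codes count under both chapters."""
    labels: set[str] = set()
    for visit in visits:
        for code in visit.codes:
            labels |= chapters_of(code)
            if not code.is_combination:
                cat = category_of(code)
                if len(cat) == 3:
                    labels.add(cat)
    return labels


def patient_level_category_rates(
    cohort: Cohort, taxonomy: CodeTaxonomy | None = None
) -> FrequencyTable:
    """Fraction of patients with each chapter/category before onset
    (comorbidity counting: combinations contribute to both chapters)."""
    taxonomy = taxonomy or CodeTaxonomy()
    counts: Counter[str] = Counter()
    for traj, onset in cohort:
        pre, _post = split_pre_post(traj, onset)
        counts.update(_patient_pre_onset_labels(pre, taxonomy))
    return FrequencyTable(level="patient_any", rows=list(counts.items()), denominator=len(cohort))


def prior_diagnosis_fraction(cohort: Cohort) -> float:
    """Fraction of patients with >=1 pre-onset visit carrying a non-F20 code."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    n_prior = 0
    for traj, onset in cohort:
        pre, _post = split_pre_post(traj, onset)
        if any(v.has_diagnosis for v in pre):
            n_prior += 1
    return n_prior / len(cohort)


def mean_prior_visits(cohort: Cohort, among_exposed: bool = False) -> float:
    """Mean number of pre-onset visits per patient.

    ``among_exposed=True`` averages only over patients with at least one
    pre-onset visit; the default averages over all eligible patients.
    """
    counts = [onset for _traj, onset in cohort]
    if among_exposed:
        counts = [c for c in counts if c > 0]
    if not counts:
        return 0.0
    return sum(counts) / len(counts)
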