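"""Data model for psychiatric-registry visits and the ICD-10 F-chapter taxonomy.

A registry row is one outpatient visit: a patient identifier, a visit date,
and up to two ICD-10 diagnosis codes (either or both may be missing).
Legacy ICD-9 rows are mapped through a user-supplied crosswalk before they
enter the pipeline.

Codes are strings such as ``"F20"``, ``"F20.5"``, bare chapters such as
``"F3"`` (the registry recorded chapter-level diagnoses), or chapter
combinations such as ``"F1-F3"`` used to render comorbid visits.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "DiagnosisCode",
    "VisitRecord",
    "PatientTrajectory",
    "CodeTaxonomy",
    "CodeError",
    "SchemaError",
    "Icd9Conversion",
    "DEFAULT_SCHEMA",
    "DEFAULT_ICD9_CROSSWALK",
    "chapters_of",
    "category_of",
    "is_schizophrenia",
    "render_label",
    "convert_icd9",
    "load_crosswalk",
    "read_visits",
    "write_visits",
]

_SIMPLE_RE = re.compile(r"^F(\d+)(?:\.(\d+))?$")
_COMBO_RE = re.compile(r"^F(\d)-F(\d)$")

#: Column-name schema for registry CSV files (override any entry).
DEFAULT_SCHEMA: dict[str, str] = {
    "patient_id": "patient_id",
    "visit_date": "visit_date",
    "dx1": "dx1",
    "dx2": "dx2",
}


class CodeError(ValueError):
    """Raised for unparsable or mis-used diagnosis codes; carries the raw string."""

    def __init__(self, raw: str, message: str):
        self.raw = raw
        super().__init__(f"{message}: {raw!r}")


class SchemaError(ValueError):
    """Raised when an input file does not match the declared column schema."""


@dataclass(frozen=True)
class DiagnosisCode:
    """A single recorded diagnosis.

    ``raw`` is either ``F<digits>[.<digits>]`` or a two-chapter combination
    ``F<d>-F<d>`` with distinct chapters.
    """

    raw: str

    def __post_init__(self) -> None:
        m = _COMBO_RE.match(self.raw)
        if m:
            if m.group(1) == m.group(2):
                raise CodeError(self.raw, "combination code must join two distinct chapters")
            return
        if not _SIMPLE_RE.match(self.raw):
            raise CodeError(self.raw, "unparsable diagnosis code")

    @property
    def is_combination(self) -> bool:
        return "-" in self.raw

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.raw


@dataclass(frozen=True)
class VisitRecord:
    """One outpatient visit; at most two diagnosis codes, possibly none."""

    patient_id: str
    visit_date: date
    codes: tuple[DiagnosisCode, ...] = ()
    source: str = "ICD10"

    def __post_init__(self) -> None:
        if len(self.codes) > 2:
            raise ValueError(
                f"visit for patient {self.patient_id!r} on {self.visit_date} "
                f"carries {len(self.codes)} codes; at most 2 are recorded per visit"
            )
        if not isinstance(self.visit_date, date):
            raise TypeError(f"visit_date must be a date, got {type(self.visit_date).__name__}")

    @property
    def has_diagnosis(self) -> bool:
        return len(self.codes) > 0


@dataclass
class PatientTrajectory:
    """All visits of one patient, sorted ascending by date."""

    patient_id: str
    visits: list[VisitRecord]

    def __post_init__(self) -> None:
        if not self.visits:
            raise ValueError(f"trajectory for {self.patient_id!r} has no visits")
        for v in self.visits:
            if v.patient_id != self.patient_id:
                raise ValueError(
                    f"visit patient_id {v.patient_id!r} != trajectory {self.patient_id!r}"
                )
        dates = [v.visit_date for v in self.visits]
        if dates != sorted(dates):
            raise ValueError(f"visits of {self.patient_id!r} are not date-sorted")

    def __len__(self) -> int:
        return len(self.visits)


def chapters_of(code: DiagnosisCode | str) -> set[str]:
    """Chapter labels of a code: ``"F31" -> {"F3"}``, ``"F1-F3" -> {"F1", "F3"}``.

    Combination codes expand to both chapters, implementing the comorbidity
    convention under which e.g. an F1-F3 record counts under F1 and under F3.
    """
    code = DiagnosisCode(code) if isinstance(code, str) else code
    m = _COMBO_RE.match(code.raw)
    if m:
        return {f"F{m.group(1)}", f"F{m.group(2)}"}
    return {code.raw[:2]}


def category_of(code: DiagnosisCode | str) -> str:
    """3-character ICD-10 category (``"F20.5" -> "F20"``).

    Bare chapter codes are legal registry observations and are returned
    unchanged (``"F4" -> "F4"``). Combination codes have no single category;
    expand them with :func:`chapters_of` first.
    """
    code = DiagnosisCode(code) if isinstance(code, str) else code
    if code.is_combination:
        raise CodeError(code.raw, "combination code has no single category")
    body = code.raw.split(".", 1)[0]
    return body[:3]


def is_schizophrenia(code: DiagnosisCode | str) -> bool:
    """True iff the code falls in ICD-10 category F20 (any F20.x).

    The bare chapter "F2" and the other psychotic-spectrum categories
    (F21-F29) do not count.
    """
    code = DiagnosisCode(code) if isinstance(code, str) else code
    if code.is_combination:
        return False
    return category_of(code) == "F20"


#: Categories rendered at 3-character level in descriptive tables; everything
#: else collapses to its chapter. Matches the granularity of the published
#: frequency tables (psychotic-spectrum categories kept apart).
F2_DETAIL: frozenset[str] = frozenset({"F20", "F21", "F22", "F23", "F24", "F25", "F28", "F29"})


def render_label(code: DiagnosisCode | str, detail: frozenset[str] | set[str] = F2_DETAIL) -> str:
    """Render a non-combination code at table granularity.

    Codes whose 3-character category is in ``detail`` keep the category label;
    all others collapse to the 2-character chapter. Bare chapters render as
    themselves.
    """
    code = DiagnosisCode(code) if isinstance(code, str) else code
    cat = category_of(code)
    if len(cat) < 3:
        return cat
    return cat if cat in detail else cat[:2]


@dataclass
class CodeTaxonomy:
    """Chapter / category / rendered-label views over diagnosis codes.

    ``detail`` controls which 3-character categories survive rendering;
    the default keeps the psychotic-spectrum categories and collapses the
    rest to chapters.
    """

    detail: frozenset[str] = F2_DETAIL

    def chapters(self, code: DiagnosisCode | str) -> set[str]:
        return chapters_of(code)

    def category(self, code: DiagnosisCode | str) -> str:
        return category_of(code)

    def render(self, code: DiagnosisCode | str) -> str:
        return render_label(code, self.detail)

    def render_visit(self, visit: VisitRecord) -> list[str]:
        """Rendered label of each code of a visit (combinations expand to chapters)."""
        labels: list[str] = []
        for c in visit.codes:
            if c.is_combination:
                labels.extend(sorted(chapters_of(c)))
            else:
                labels.append(self.render(c))
        return labels


# --- ICD-9 conversion -------------------------------------------------------

#: Minimal chapter-level crosswalk for the common psychiatric ICD-9 ranges.
#: Intentionally coarse; supply a fuller two-column CSV for production use.
DEFAULT_ICD9_CROSSWALK: dict[str, str] = {
    "290": "F0", "291": "F1", "292": "F1", "293": "F0", "294": "F0",
    "295": "F20", "296": "F3", "297": "F22", "298": "F23", "299": "F8",
    "300": "F4", "301": "F6", "302": "F6", "303": "F1", "304": "F1",
    "305": "F1", "306": "F4", "307": "F5", "308": "F4", "309": "F4",
    "310": "F0", "311": "F3", "312": "F9", "313": "F9", "314": "F9",
    "315": "F8", "316": "F5", "317": "F7", "318": "F7", "319": "F7",
}


@dataclass(frozen=True)
class Icd9Conversion:
    """Result of mapping one ICD-9 code: either a mapped ICD-10 code, or the
    raw ICD-9 string passed through with ``mapped=False``."""

    icd9: str
    code: DiagnosisCode | None
    mapped: bool


def load_crosswalk(path: str | Path) -> dict[str, str]:
    """Load a two-column (icd9, icd10) CSV crosswalk, validating every target."""
    table: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise SchemaError(f"crosswalk {path}: expected two columns (icd9, icd10)")
        for lineno, row in enumerate(reader, start=2):
            if not row or not row[0].strip():
                continue
            icd9, icd10 = row[0].strip(), row[1].strip()
            try:
                DiagnosisCode(icd10)
            except CodeError as exc:
                raise CodeError(icd10, f"crosswalk {path} line {lineno}: bad ICD-10 target") from exc
            table[icd9] = icd10
    return table


def convert_icd9(code: str, crosswalk: Mapping[str, str] | None = None) -> Icd9Conversion:
    """Map one ICD-9 code through the crosswalk.

    Lookup tries the full code first, then its 3-digit prefix. Unmapped codes
    pass through flagged, never raise.
    """
    table = DEFAULT_ICD9_CROSSWALK if crosswalk is None else crosswalk
    target = table.get(code)
    if target is None:
        target = table.get(code.split(".", 1)[0])
    if target is None:
        return Icd9Conversion(icd9=code, code=None, mapped=False)
    return Icd9Conversion(icd9=code, code=DiagnosisCode(target), mapped=True)


# --- CSV I/O ----------------------------------------------------------------


def _parse_date(value: str, row_number: int) -> date:
    try:
        return datetime.strptime(value, "%Y-%m-%d").date()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"row {row_number}: malformed visit_date {value!r} (expected ISO-8601)") from exc


def read_visits(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[PatientTrajectory]:
    """Read a registry CSV into per-patient, date-sorted trajectories.

    The file must carry the four schema columns (default names
    ``patient_id, visit_date, dx1, dx2``); empty dx cells mean the diagnosis
    was not recorded. Sorting is stable, so same-day visits keep input order.
    """
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: columns {missing} not found (file has {list(df.columns)}); "
            "pass a schema mapping if the file uses different names"
        )

    records: dict[str, list[VisitRecord]] = {}
    order: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        pid = row[cols["patient_id"]]
        visit_date = _parse_date(row[cols["visit_date"]], i)
        codes = tuple(
            DiagnosisCode(row[cols[c]].strip())
            for c in ("dx1", "dx2")
            if row[cols[c]].strip()
        )
        if pid not in records:
            records[pid] = []
            order.append(pid)
        records[pid].append(VisitRecord(patient_id=pid, visit_date=visit_date, codes=codes))

    out: list[PatientTrajectory] = []
    for pid in order:
        visits = sorted(records[pid], key=lambda v: v.visit_date)  # stable
        out.append(PatientTrajectory(patient_id=pid, visits=visits))
    return out


def write_visits(
    trajectories: Iterable[PatientTrajectory],
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> None:
    """Write trajectories back to the registry CSV schema (inverse of read_visits)."""
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    rows = []
    for traj in trajectories:
        for v in traj.visits:
            rows.append(
                {
                    cols["patient_id"]: v.patient_id,
                    cols["visit_date"]: v.visit_date.isoformat(),
                    cols["dx1"]: v.codes[0].raw if len(v.codes) > 0 else "",
                    cols["dx2"]: v.codes[1].raw if len(v.codes) > 1 else "",
                }
            )
    pd.DataFrame(rows, columns=list(cols.values())).to_csv(path, index=False)
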