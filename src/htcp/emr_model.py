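"""Domain types and CSV IO for EMR extracts.

The phenotyping rules operate on two flat tables: one row per patient and
one row per dated, coded clinical event (diagnosis, procedure, medication
order, or visit).  ICD-9 diagnosis codes and HCPCS/CPT procedure codes are
kept as normalized decimal *strings* ("362.50", "J2778") — never floats —
because trailing zeros are semantically significant and prefix matching
("starting with 362.5") must operate on the literal code text.
"""

from __future__ import annotations

import datetime as dt
import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Sex",
    "EventKind",
    "Specialty",
    "MatchMode",
    "Patient",
    "ClinicalEvent",
    "CodeSet",
    "Cohort",
    "RejectedRow",
    "CohortLoadError",
    "MalformedCodeError",
    "normalize_code",
    "code_matches",
    "read_cohort",
    "write_cohort",
]


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class EventKind(str, enum.Enum):
    DIAGNOSIS = "DIAGNOSIS"
    PROCEDURE = "PROCEDURE"
    MEDICATION = "MEDICATION"
    VISIT = "VISIT"


class Specialty(str, enum.Enum):
    OPHTHALMOLOGY = "OPHTHALMOLOGY"
    OTHER = "OTHER"
    UNKNOWN = "UNKNOWN"


class MatchMode(str, enum.Enum):
    EXACT = "EXACT"
    PREFIX = "PREFIX"


class MalformedCodeError(ValueError):
    """Raised for empty/blank clinical codes."""


class CohortLoadError(ValueError):
    """Structured load failure: missing file/column or unparseable field."""


def normalize_code(raw: str) -> str:
    """Normalize a clinical code: strip whitespace, uppercase.

    Decimal points are preserved as-is ("362.50" stays "362.50").
    Idempotent: ``normalize_code(normalize_code(x)) == normalize_code(x)``.

    Raises
    ------
    MalformedCodeError
        If the input is empty or whitespace-only.
    """
    if raw is None or not str(raw).strip():
        raise MalformedCodeError(f"empty or blank clinical code: {raw!r}")
    return "".join(str(raw).split()).upper()


@dataclass(frozen=True)
class CodeSet:
    """A named set of code patterns with per-entry match semantics.

    EXACT entries match the full code string; PREFIX entries match leading
    characters.  Under this convention ``("362.5", PREFIX)`` matches the
    whole macular-degeneration family 362.50–362.57, while ``("362", EXACT)``
    matches only the bare three-digit code.
    """

    name: str
    entries: tuple[tuple[str, MatchMode], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"CodeSet {self.name!r} must have >=1 entry")
        norm = tuple(
            (normalize_code(p) if p.strip() else p.strip(), MatchMode(m))
            for p, m in self.entries
        )
        object.__setattr__(self, "entries", norm)
        for pattern, mode in self.entries:
            if mode is MatchMode.PREFIX and pattern == "":
                warnings.warn(
                    f"CodeSet {self.name!r} has an empty PREFIX pattern; "
                    "it matches every code",
                    stacklevel=2,
                )

    @classmethod
    def exact(cls, name: str, codes: Iterable[str]) -> "CodeSet":
        return cls(name, tuple((c, MatchMode.EXACT) for c in codes))

    @classmethod
    def prefix(cls, name: str, prefixes: Iterable[str]) -> "CodeSet":
        return cls(name, tuple((p, MatchMode.PREFIX) for p in prefixes))

    def union(self, other: "CodeSet", name: str | None = None) -> "CodeSet":
        return CodeSet(name or f"{self.name}|{other.name}",
                       self.entries + other.entries)


def code_matches(code: str, code_set: CodeSet) -> bool:
    """True iff any entry of ``code_set`` matches the (normalized) code."""
    for pattern, mode in code_set.entries:
        if mode is MatchMode.EXACT:
            if code == pattern:
                return True
        else:
            if code.startswith(pattern):
                return True
    return False


@dataclass(frozen=True)
class Patient:
    patient_id: str
    birth_date: dt.date
    sex: Sex = Sex.UNKNOWN
    ancestry_european: bool | None = None
    bmi: float | None = None
    smoking_ever: bool | None = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")


@dataclass(frozen=True)
class ClinicalEvent:
    patient_id: str
    event_date: dt.date
    kind: EventKind
    code: str = ""
    provider_specialty: Specialty = Specialty.UNKNOWN

    def __post_init__(self) -> None:
        if self.kind is not EventKind.VISIT and not self.code:
            raise ValueError(
                f"{self.kind.value} event for {self.patient_id} needs a code"
            )
        if self.code:
            object.__setattr__(self, "code", normalize_code(self.code))


@dataclass(frozen=True)
class RejectedRow:
    table: str
    row_number: int  # 1-based data-row number in the CSV
    reason: str


@dataclass
class Cohort:
    patients: list[Patient]
    events: list[ClinicalEvent]
    rejected: list[RejectedRow] = field(default_factory=list)

    def events_by_patient(self) -> dict[str, list[ClinicalEvent]]:
        out: dict[str, list[ClinicalEvent]] = {p.patient_id: [] for p in self.patients}
        for ev in self.events:
            out.setdefault(ev.patient_id, []).append(ev)
        return out


_PATIENT_COLS = ["patient_id", "birth_date", "sex", "ancestry_european", "bmi",
                 "smoking_ever"]
_EVENT_COLS = ["patient_id", "event_date", "kind", "code", "provider_specialty"]


def _parse_date(value: str, table: str, row: int, col: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except (ValueError, TypeError) as exc:
        raise CohortLoadError(
            f"{table} row {row}: cannot parse {col}={value!r} as ISO date"
        ) from exc


def _opt_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    s = str(value).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def _read_table(path: str | Path, cols: Sequence[str], table: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{table} table not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CohortLoadError(f"{table} table {path} missing columns: {missing}")
    return df


def read_cohort(patients_path: str | Path, events_path: str | Path) -> Cohort:
    """Load and validate a cohort from patients.csv + events.csv.

    Rows violating record invariants (event dated before the patient's
    birth, code missing on a coded event, unknown patient on an event) are
    rejected with row-numbered diagnostics in ``Cohort.rejected``; malformed
    files (missing file/column, unparseable date) raise instead.
    """
    pdf = _read_table(patients_path, _PATIENT_COLS, "patients")
    edf = _read_table(events_path, _EVENT_COLS, "events")

    rejected: list[RejectedRow] = []
    patients: list[Patient] = []
    seen: dict[str, dt.date] = {}
    for i, row in enumerate(pdf.itertuples(index=False), start=1):
        birth = _parse_date(row.birth_date, "patients", i, "birth_date")
        pid = str(row.patient_id)
        if pid in seen:
            rejected.append(RejectedRow("patients", i, f"duplicate patient_id {pid!r}"))
            continue
        try:
            patients.append(Patient(
                patient_id=pid,
                birth_date=birth,
                sex=Sex(str(row.sex).strip().lower() or "unknown"),
                ancestry_european=_opt_bool(row.ancestry_european),
                bmi=float(row.bmi) if str(row.bmi).strip() else None,
                smoking_ever=_opt_bool(row.smoking_ever),
            ))
        except ValueError as exc:
            rejected.append(RejectedRow("patients", i, str(exc)))
            continue
        seen[pid] = birth

    events: list[ClinicalEvent] = []
    for i, row in enumerate(edf.itertuples(index=False), start=1):
        date = _parse_date(row.event_date, "events", i, "event_date")
        pid = str(row.patient_id)
        if pid not in seen:
            rejected.append(RejectedRow("events", i, f"unknown patient_id {pid!r}"))
            continue
        if date < seen[pid]:
            rejected.append(RejectedRow(
                "events", i, f"event date {date} precedes birth date {seen[pid]}"
            ))
            continue
        try:
            events.append(ClinicalEvent(
                patient_id=pid,
                event_date=date,
                kind=EventKind(str(row.kind).strip().upper()),
                code=str(row.code).strip(),
                provider_specialty=Specialty(
                    str(row.provider_specialty).strip().upper() or "UNKNOWN"),
            ))
        except ValueError as exc:
            rejected.append(RejectedRow("events", i, str(exc)))
    return Cohort(patients=patients, events=events, rejected=rejected)


def write_cohort(cohort: Cohort, patients_path: str | Path,
                 events_path: str | Path) -> None:
    """Write a cohort back to the two-table CSV layout (lossless round trip)."""
    def _b(v):  # booleans as lowercase tokens, None as empty
        return "" if v is None else str(bool(v)).lower()

    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "birth_date": p.birth_date.isoformat(),
                "sex": p.sex.value,
                "ancestry_european": _b(p.ancestry_european),
                "bmi": "" if p.bmi is None else repr(float(p.bmi)),
                "smoking_ever": _b(p.smoking_ever),
            }
            for p in cohort.patients
        ],
        columns=_PATIENT_COLS,
    ).to_csv(patients_path, index=False)
    pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "event_date": e.event_date.isoformat(),
                "kind": e.kind.value,
                "code": e.code,
                "provider_specialty": e.provider_specialty.value,
            }
            for e in cohort.events
        ],
        columns=_EVENT_COLS,
    ).to_csv(events_path, index=False)
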