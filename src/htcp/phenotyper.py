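"""Rule-based EMR phenotyping of AMD cases, subtypes, and controls.

Each patient is assigned exactly one of WET_AMD / DRY_AMD / CONTROL /
UNCLASSIFIED from their coded events:

* **case** — diagnoses from the AMD ICD-9 family (362.50, 362.51, 362.52,
  362.16, 362.57) entered by an ophthalmologist on at least
  ``min_amd_dx_dates`` distinct calendar dates, with the patient aged
  ``min_age_years`` or older at the first such date;
* **wet** — among cases, an anti-VEGF injection (HCPCS J2778 / J9035 /
  J3490 / J3590 procedure, or a ranibizumab / bevacizumab / aflibercept
  medication order) accompanied by an ICD-9 code starting with 362.5 on the
  same calendar date;
* **control** — no AMD(-associated) diagnosis ever, plus an ophthalmology
  visit in the two years before the index date, aged 60+ at that visit.

Two rule versions are supported: V1 is the initial pilot form (any single
qualifying diagnosis, no age gates, injections count toward wet without the
same-date diagnosis); V2 adds the refinements above.  V2 case criteria are
strictly stronger than V1's, so every V2 case is also a V1 case.
"""

from __future__ import annotations

import datetime as dt
import enum
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .emr_model import (
    ClinicalEvent,
    CodeSet,
    Cohort,
    EventKind,
    MatchMode,
    Patient,
    Specialty,
    code_matches,
    normalize_code,
)

__all__ = [
    "Label",
    "AlgorithmVersion",
    "AlgorithmConfig",
    "Evidence",
    "PhenotypeLabel",
    "age_at",
    "amd_diagnosis_dates",
    "is_amd_case",
    "is_wet",
    "is_control",
    "classify_patient",
    "classify_cohort",
    "DEFAULT_AMD_DX_CODES",
    "DEFAULT_WET_PROC_CODES",
    "DEFAULT_WET_MED_NAMES",
]


class Label(str, enum.Enum):
    WET_AMD = "WET_AMD"
    DRY_AMD = "DRY_AMD"
    CONTROL = "CONTROL"
    UNCLASSIFIED = "UNCLASSIFIED"


class AlgorithmVersion(str, enum.Enum):
    V1 = "V1"  # initial pilot rules
    V2 = "V2"  # refined, chart-review-validated rules


DEFAULT_AMD_DX_CODES = CodeSet.exact(
    "amd_dx", ["362.50", "362.51", "362.52", "362.16", "362.57"])
# J2778 ranibizumab; J9035/J3490/J3590 bevacizumab. HCPCS Level II codes,
# stored in the PROCEDURE namespace alongside CPT.
DEFAULT_WET_PROC_CODES = CodeSet.exact(
    "anti_vegf_proc", ["J2778", "J9035", "J3490", "J3590"])
DEFAULT_WET_MED_NAMES = (
    "ranibizumab", "lucentis",
    "bevacizumab", "avastin",
    "aflibercept", "eylea",
)
DEFAULT_WET_SAME_DATE_DX = CodeSet.prefix("amd_362_5_family", ["362.5"])
# Controls must carry no AMD or AMD-associated diagnosis.  The non-specific
# codes bare "362" and "377.21" are deliberately absent from this set: they
# do not disqualify a control.
DEFAULT_CONTROL_EXCLUSION = DEFAULT_AMD_DX_CODES.union(
    DEFAULT_WET_SAME_DATE_DX, name="control_exclusion")


@dataclass(frozen=True)
class AlgorithmConfig:
    index_date: dt.date
    version: AlgorithmVersion = AlgorithmVersion.V2
    amd_dx_codes: CodeSet = DEFAULT_AMD_DX_CODES
    wet_proc_codes: CodeSet = DEFAULT_WET_PROC_CODES
    wet_med_names: tuple[str, ...] = DEFAULT_WET_MED_NAMES
    wet_same_date_dx: CodeSet = DEFAULT_WET_SAME_DATE_DX
    min_amd_dx_dates: int = 2
    min_age_years: int = 60
    control_lookback_years: float = 2.0
    control_exclusion_codes: CodeSet = DEFAULT_CONTROL_EXCLUSION
    require_ophthalmologist_dx: bool = True

    def __post_init__(self) -> None:
        if self.min_amd_dx_dates < 1:
            raise ValueError("min_amd_dx_dates must be >= 1")
        if self.control_lookback_years <= 0:
            raise ValueError("control_lookback_years must be > 0")
        if not isinstance(self.index_date, dt.date):
            raise TypeError("index_date must be an explicit calendar date")
        object.__setattr__(
            self, "wet_med_names",
            tuple(m.strip().lower() for m in self.wet_med_names))

    @classmethod
    def v1(cls, index_date: dt.date, **kw) -> "AlgorithmConfig":
        kw.setdefault("min_amd_dx_dates", 1)
        return cls(index_date=index_date, version=AlgorithmVersion.V1, **kw)

    @classmethod
    def v2(cls, index_date: dt.date, **kw) -> "AlgorithmConfig":
        return cls(index_date=index_date, version=AlgorithmVersion.V2, **kw)

    @property
    def _age_gated(self) -> bool:
        return self.version is AlgorithmVersion.V2

    def as_v1(self) -> "AlgorithmConfig":
        return replace(self, version=AlgorithmVersion.V1, min_amd_dx_dates=1)


@dataclass(frozen=True)
class Evidence:
    criterion: str
    satisfied: bool
    events: tuple[str, ...] = ()  # ISO dates / codes supporting the finding


@dataclass(frozen=True)
class PhenotypeLabel:
    value: Label
    evidence: tuple[Evidence, ...]

    def evidence_json(self) -> str:
        return json.dumps(
            [
                {"criterion": e.criterion, "satisfied": e.satisfied,
                 "events": list(e.events)}
                for e in self.evidence
            ]
        )


def age_at(patient: Patient, date: dt.date) -> int:
    """Completed whole years of age at ``date`` (clinical floor convention)."""
    if date < patient.birth_date:
        raise ValueError(
            f"date {date} precedes birth date {patient.birth_date} "
            f"for patient {patient.patient_id}")
    b = patient.birth_date
    return date.year - b.year - ((date.month, date.day) < (b.month, b.day))


def _qualifying_dx(ev: ClinicalEvent, codes: CodeSet,
                   require_ophtho: bool) -> bool:
    if ev.kind is not EventKind.DIAGNOSIS:
        return False
    if require_ophtho and ev.provider_specialty is not Specialty.OPHTHALMOLOGY:
        return False
    return code_matches(ev.code, codes)


def amd_diagnosis_dates(events: Iterable[ClinicalEvent],
                        config: AlgorithmConfig) -> list[dt.date]:
    """Distinct ascending calendar dates bearing a qualifying AMD diagnosis.

    Distinct *dates*, not rows: EMRs duplicate codes within one encounter,
    so distinct dates approximate distinct visits.
    """
    dates = {
        ev.event_date
        for ev in events
        if _qualifying_dx(ev, config.amd_dx_codes,
                          config.require_ophthalmologist_dx)
    }
    return sorted(dates)


def is_amd_case(patient: Patient, events: Sequence[ClinicalEvent],
                config: AlgorithmConfig) -> tuple[bool, list[Evidence]]:
    dates = amd_diagnosis_dates(events, config)
    ev: list[Evidence] = [
        Evidence(
            f"amd_dx_on_>={config.min_amd_dx_dates}_distinct_dates",
            len(dates) >= config.min_amd_dx_dates,
            tuple(d.isoformat() for d in dates),
        )
    ]
    ok = len(dates) >= config.min_amd_dx_dates
    if config._age_gated:
        if dates:
            age = age_at(patient, dates[0])
            age_ok = age >= config.min_age_years
            ev.append(Evidence(
                f"age_at_first_amd_dx_>={config.min_age_years}",
                age_ok, (dates[0].isoformat(), f"age={age}")))
        else:
            age_ok = False
            ev.append(Evidence(
                f"age_at_first_amd_dx_>={config.min_age_years}", False))
        ok = ok and age_ok
    return ok, ev


def is_wet(patient: Patient, events: Sequence[ClinicalEvent],
           config: AlgorithmConfig) -> tuple[bool, list[Evidence]]:
    """Wet-AMD criterion; evaluate only for established cases."""
    def _is_injection(e: ClinicalEvent) -> bool:
        if e.kind is EventKind.PROCEDURE:
            return code_matches(e.code, config.wet_proc_codes)
        if e.kind is EventKind.MEDICATION:
            return e.code.lower() in config.wet_med_names
        return False

    injections = [e for e in events if _is_injection(e)]
    if config.version is AlgorithmVersion.V1:
        ok = bool(injections)
        return ok, [Evidence(
            "anti_vegf_injection_or_order", ok,
            tuple(sorted({e.event_date.isoformat() for e in injections})))]

    dx_dates_3625 = {
        e.event_date for e in events
        if e.kind is EventKind.DIAGNOSIS
        and code_matches(e.code, config.wet_same_date_dx)
    }
    hits = sorted({e.event_date for e in injections} & dx_dates_3625)
    ok = bool(hits)
    return ok, [Evidence(
        "anti_vegf_with_same_date_362.5x_dx", ok,
        tuple(d.isoformat() for d in hits))]


def is_control(patient: Patient, events: Sequence[ClinicalEvent],
               config: AlgorithmConfig) -> tuple[bool, list[Evidence]]:
    lookback_days = round(config.control_lookback_years * 365.25)
    window_start = config.index_date - dt.timedelta(days=lookback_days)

    def _in_window(d: dt.date) -> bool:
        return window_start < d <= config.index_date  # half-open (start, index]

    ophtho_visits = [
        e for e in events
        if e.provider_specialty is Specialty.OPHTHALMOLOGY
        and _in_window(e.event_date)
    ]
    if config._age_gated:
        ophtho_visits = [
            e for e in ophtho_visits
            if age_at(patient, e.event_date) >= config.min_age_years
        ]
    visit_ok = bool(ophtho_visits)
    excl = [
        e for e in events
        if e.kind is EventKind.DIAGNOSIS
        and code_matches(e.code, config.control_exclusion_codes)
    ]
    no_amd = not excl
    ev = [
        Evidence(
            "ophthalmology_visit_in_lookback"
            + ("_age_gated" if config._age_gated else ""),
            visit_ok,
            tuple(sorted({e.event_date.isoformat() for e in ophtho_visits})),
        ),
        Evidence(
            "no_amd_or_associated_dx_ever", no_amd,
            tuple(sorted({e.code for e in excl})),
        ),
    ]
    return visit_ok and no_amd, ev


def classify_patient(patient: Patient, events: Sequence[ClinicalEvent],
                     config: AlgorithmConfig) -> PhenotypeLabel:
    """Assign one label; case criteria are evaluated before control criteria."""
    case, case_ev = is_amd_case(patient, events, config)
    if case:
        wet, wet_ev = is_wet(patient, events, config)
        return PhenotypeLabel(
            Label.WET_AMD if wet else Label.DRY_AMD,
            tuple(case_ev + wet_ev))
    control, ctrl_ev = is_control(patient, events, config)
    return PhenotypeLabel(
        Label.CONTROL if control else Label.UNCLASSIFIED,
        tuple(case_ev + ctrl_ev))


def classify_cohort(cohort: Cohort, config: AlgorithmConfig
                    ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label every patient; returns (per-patient table, class counts).

    Deterministic and order-independent: output rows are sorted by
    patient_id.  Duplicate patient ids are an error.
    """
    ids = [p.patient_id for p in cohort.patients]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient_id(s): {dupes}")
    by_patient = cohort.events_by_patient()
    rows = []
    for p in sorted(cohort.patients, key=lambda q: q.patient_id):
        events = by_patient.get(p.patient_id, [])
        lab = classify_patient(p, events, config)
        dx = amd_diagnosis_dates(events, config)
        rows.append({
            "patient_id": p.patient_id,
            "label": lab.value.value,
            "first_amd_dx_date": dx[0].isoformat() if dx else "",
            "evidence_json": lab.evidence_json(),
        })
    table = pd.DataFrame(
        rows, columns=["patient_id", "label", "first_amd_dx_date",
                       "evidence_json"])
    counts = {lab.value: 0 for lab in Label}
    for r in rows:
        counts[r["label"]] += 1
    return table, counts
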