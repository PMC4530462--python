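"""Synthetic EMR cohort generator with planted ground truth.

Generates patients, coded clinical events and a truth table emulating an
academic-center ophthalmology population: true dry/wet AMD, AMD-mimicking
retinal disease (diabetic retinopathy, pattern dystrophy, central serous
chorioretinopathy, polypoidal choroidal vasculopathy, macular scar), and
healthy patients.  Configurable noise knobs plant the coding-error modes
that break rule-based phenotyping in practice:

* ``p_miscode_amd`` — a mimicker also receives AMD ICD-9 codes (and, for
  wet-like mimickers such as PCV, anti-VEGF injections), producing false
  positives;
* ``p_missed_second_visit`` — a true case is coded on only one date,
  failing the two-date criterion;
* ``p_injection_coded_same_date`` — whether a wet case's injection carries
  a same-date 362.5x diagnosis (when it does not, the wet criterion fails
  and the case degrades to dry);
* ``p_specialty_other`` — a diagnosis is entered by a non-ophthalmologist.

Each patient consumes an independent pseudo-random stream derived from
``(seed, patient index)``, so cohorts are reproducible and growing
``n_patients`` extends a cohort without reshuffling existing patients.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .emr_model import (
    ClinicalEvent,
    Cohort,
    EventKind,
    Patient,
    Sex,
    Specialty,
    write_cohort,
)
from .validation import ExpertLabel

__all__ = [
    "TruePhenotype",
    "TruthRecord",
    "SimulationConfig",
    "simulate_cohort",
    "truth_to_expert_labels",
    "write_truth",
    "read_truth",
    "MIMICKER_CODES",
]


class TruePhenotype(str, enum.Enum):
    TRUE_DRY = "TRUE_DRY"
    TRUE_WET = "TRUE_WET"
    MIMICKER = "MIMICKER"
    HEALTHY = "HEALTHY"


@dataclass(frozen=True)
class TruthRecord:
    patient_id: str
    true_phenotype: TruePhenotype
    mimicker_type: str | None = None


# ICD-9 codes for the mimicker diagnoses themselves (none in the AMD code
# set, none in the 362.5x family).  "wet_like" mimickers receive anti-VEGF
# injections when miscoded, reproducing the PCV-style false positive.
MIMICKER_CODES: dict[str, dict] = {
    "diabetic_retinopathy": {"code": "362.01", "wet_like": False},
    "pattern_dystrophy": {"code": "362.76", "wet_like": False},
    "central_serous_chorioretinopathy": {"code": "362.41", "wet_like": False},
    "polypoidal_choroidal_vasculopathy": {"code": "363.8", "wet_like": True},
    "macular_scar": {"code": "363.32", "wet_like": True},
}

_AMD_DRY_CODES = ("362.50", "362.51", "362.57", "362.16")
_AMD_WET_CODE = "362.52"
_INJECTION_CODES = ("J2778", "J9035")
_INJECTION_MEDS = ("ranibizumab", "bevacizumab", "aflibercept")


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int
    seed: int
    index_date: dt.date = dt.date(2014, 1, 1)
    # truncated normal in years; the cohort deliberately spans well below
    # the 60-year gate so age criteria are exercised
    age_distribution: tuple[float, float, float, float] = (70.0, 12.0, 40.0, 95.0)
    prevalence: dict = field(default_factory=lambda: {
        "true_dry": 0.05, "true_wet": 0.03, "mimicker": 0.07, "healthy": 0.85})
    mimicker_types: tuple[str, ...] = tuple(MIMICKER_CODES)
    p_miscode_amd: float = 0.10
    p_missed_second_visit: float = 0.05
    p_injection_coded_same_date: float = 0.90
    visit_rate: float = 1.5  # mean ophthalmology visits / year
    p_specialty_other: float = 0.05

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        total = sum(self.prevalence.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"prevalence must sum to 1, got {total}")
        for name in ("p_miscode_amd", "p_missed_second_visit",
                     "p_injection_coded_same_date", "p_specialty_other"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        unknown = set(self.mimicker_types) - set(MIMICKER_CODES)
        if unknown:
            raise ValueError(f"unknown mimicker types: {sorted(unknown)}")


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _dx_specialty(rng: np.random.Generator, cfg: SimulationConfig) -> Specialty:
    return (Specialty.OTHER if rng.random() < cfg.p_specialty_other
            else Specialty.OPHTHALMOLOGY)


def _random_dates(rng: np.random.Generator, n: int, index: dt.date,
                  max_back_days: int, min_back_days: int = 0) -> list[dt.date]:
    """n distinct dates within (index - max_back, index - min_back]."""
    if n <= 0:
        return []
    span = max(max_back_days - min_back_days, n)
    offs: set[int] = set()
    while len(offs) < n:
        offs.add(min_back_days + int(rng.integers(0, span)))
    return sorted(index - dt.timedelta(days=o) for o in offs)


def _simulate_patient(i: int, cfg: SimulationConfig
                      ) -> tuple[Patient, list[ClinicalEvent], TruthRecord]:
    rng = _patient_rng(cfg.seed, i)
    pid = f"P{i:06d}"

    age = _truncnorm(rng, *cfg.age_distribution)
    birth = cfg.index_date - dt.timedelta(days=round(age * 365.25))
    patient = Patient(
        patient_id=pid,
        birth_date=birth,
        sex=Sex.FEMALE if rng.random() < 0.6 else Sex.MALE,
        ancestry_european=bool(rng.random() < 0.85),
        bmi=float(np.round(_truncnorm(rng, 27.5, 4.5, 16, 45), 1)),
        smoking_ever=bool(rng.random() < 0.5),
    )

    classes = ("true_dry", "true_wet", "mimicker", "healthy")
    probs = np.array([cfg.prevalence[c] for c in classes])
    cls = classes[int(rng.choice(len(classes), p=probs))]

    events: list[ClinicalEvent] = []
    horizon = round(10 * 365.25)  # all events within (index - 10y, index]

    # background ophthalmology visits over the last two years keep control
    # eligibility realistic for every class
    n_visits = rng.poisson(cfg.visit_rate * 2)
    for d in _random_dates(rng, max(n_visits, 1), cfg.index_date,
                           round(2 * 365.25)):
        events.append(ClinicalEvent(pid, d, EventKind.VISIT,
                                    provider_specialty=Specialty.OPHTHALMOLOGY))

    if cls in ("true_dry", "true_wet"):
        truth = TruthRecord(pid, TruePhenotype[cls.upper()])
        n_dx = 1 if rng.random() < cfg.p_missed_second_visit \
            else 2 + int(rng.integers(0, 4))
        dx_dates = _random_dates(rng, n_dx, cfg.index_date,
                                 round(5 * 365.25))
        for d in dx_dates:
            code = _AMD_WET_CODE if (cls == "true_wet" and rng.random() < 0.7) \
                else str(rng.choice(_AMD_DRY_CODES))
            events.append(ClinicalEvent(pid, d, EventKind.DIAGNOSIS, code,
                                        _dx_specialty(rng, cfg)))
        if cls == "true_wet":
            n_inj = 1 + int(rng.integers(0, 6))
            inj_dates = _random_dates(rng, n_inj, cfg.index_date,
                                      round(3 * 365.25))
            for d in inj_dates:
                if rng.random() < 0.8:
                    events.append(ClinicalEvent(
                        pid, d, EventKind.PROCEDURE,
                        str(rng.choice(_INJECTION_CODES)),
                        Specialty.OPHTHALMOLOGY))
                else:
                    events.append(ClinicalEvent(
                        pid, d, EventKind.MEDICATION,
                        str(rng.choice(_INJECTION_MEDS)),
                        Specialty.OPHTHALMOLOGY))
                if rng.random() < cfg.p_injection_coded_same_date:
                    events.append(ClinicalEvent(
                        pid, d, EventKind.DIAGNOSIS, _AMD_WET_CODE,
                        _dx_specialty(rng, cfg)))
    elif cls == "mimicker":
        mtype = str(rng.choice(np.array(cfg.mimicker_types, dtype=object)))
        truth = TruthRecord(pid, TruePhenotype.MIMICKER, mtype)
        info = MIMICKER_CODES[mtype]
        for d in _random_dates(rng, 1 + int(rng.integers(0, 3)),
                               cfg.index_date, round(5 * 365.25)):
            events.append(ClinicalEvent(pid, d, EventKind.DIAGNOSIS,
                                        info["code"],
                                        _dx_specialty(rng, cfg)))
        if rng.random() < cfg.p_miscode_amd:
            # the miscoding failure mode: AMD family codes on >=2 dates;
            # wet-like mimickers also receive injections with same-date
            # 362.5x codes, imitating a wet case end to end
            mis_dates = _random_dates(rng, 2, cfg.index_date,
                                      round(4 * 365.25))
            mis_code = _AMD_WET_CODE if info["wet_like"] \
                else str(rng.choice(_AMD_DRY_CODES))
            for d in mis_dates:
                events.append(ClinicalEvent(pid, d, EventKind.DIAGNOSIS,
                                            mis_code,
                                            _dx_specialty(rng, cfg)))
            if info["wet_like"]:
                events.append(ClinicalEvent(
                    pid, mis_dates[0], EventKind.PROCEDURE,
                    str(rng.choice(_INJECTION_CODES)),
                    Specialty.OPHTHALMOLOGY))
    else:
        truth = TruthRecord(pid, TruePhenotype.HEALTHY)
        if rng.random() < 0.3:  # unrelated, non-disqualifying diagnoses
            d = _random_dates(rng, 1, cfg.index_date, horizon)[0]
            events.append(ClinicalEvent(pid, d, EventKind.DIAGNOSIS,
                                        str(rng.choice(("366.16", "365.01",
                                                        "377.21", "362"))),
                                        _dx_specialty(rng, cfg)))

    events.sort(key=lambda e: (e.event_date, e.kind.value, e.code))
    return patient, events, truth


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[Cohort, list[TruthRecord]]:
    """Deterministic cohort generation; same config -> identical output."""
    patients, events, truths = [], [], []
    for i in range(config.n_patients):
        p, ev, t = _simulate_patient(i, config)
        patients.append(p)
        events.extend(ev)
        truths.append(t)
    return Cohort(patients=patients, events=events), truths


def truth_to_expert_labels(truths: Sequence[TruthRecord]
                           ) -> dict[str, ExpertLabel]:
    """Map planted truth to gold-standard chart-review labels."""
    mapping = {TruePhenotype.TRUE_DRY: ExpertLabel.DRY_AMD,
               TruePhenotype.TRUE_WET: ExpertLabel.WET_AMD}
    return {t.patient_id: mapping.get(t.true_phenotype, ExpertLabel.NOT_AMD)
            for t in truths}


def write_truth(truths: Sequence[TruthRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"patient_id": t.patient_id,
          "true_phenotype": t.true_phenotype.value,
          "mimicker_type": t.mimicker_type or ""} for t in truths]
    ).to_csv(path, index=False)


def read_truth(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        TruthRecord(r.patient_id, TruePhenotype(r.true_phenotype),
                    r.mimicker_type or None)
        for r in df.itertuples(index=False)
    ]
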