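import datetime as dt

import pytest

from htcp.emr_model import ClinicalEvent, EventKind, Patient, Sex, Specialty
from htcp.phenotyper import AlgorithmConfig

INDEX = dt.date(2014, 1, 1)


@pytest.fixture
def v2_config() -> AlgorithmConfig:
    return AlgorithmConfig.v2(index_date=INDEX)


@pytest.fixture
def v1_config() -> AlgorithmConfig:
    return AlgorithmConfig.v1(index_date=INDEX)


@pytest.fixture
def patient_70() -> Patient:
    # aged 70 at the index date
    return Patient("pt1", dt.date(1944, 1, 1), sex=Sex.FEMALE)


def dx(date, code, pid="pt1", specialty=Specialty.OPHTHALMOLOGY):
    return ClinicalEvent(pid, date, EventKind.DIAGNOSIS, code, specialty)


def proc(date, code, pid="pt1"):
    return ClinicalEvent(pid, date, EventKind.PROCEDURE, code,
                         Specialty.OPHTHALMOLOGY)


def med(date, name, pid="pt1"):
    return ClinicalEvent(pid, date, EventKind.MEDICATION, name,
                         Specialty.OPHTHALMOLOGY)


def visit(date, pid="pt1", specialty=Specialty.OPHTHALMOLOGY):
    return ClinicalEvent(pid, date, EventKind.VISIT, "", specialty)
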