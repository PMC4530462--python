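"""YAML configuration loading with the reference defaults pre-filled."""

from __future__ import annotations

import datetime as dt
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .emr_model import CodeSet, MatchMode
from .phenotyper import AlgorithmConfig, AlgorithmVersion
from .synthetic_emr import SimulationConfig
from .association import AssociationConfig

__all__ = ["reference_defaults", "load_yaml", "algorithm_config_from_dict",
           "simulation_config_from_dict", "association_config_from_dict"]


def reference_defaults() -> dict:
    """The packaged reference configuration (code sets, thresholds, panel)."""
    text = (resources.files("htcp") / "reference_defaults.yaml").read_text()
    return yaml.safe_load(text)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _code_set(name: str, spec: Mapping[str, Any]) -> CodeSet:
    entries: list[tuple[str, MatchMode]] = []
    for code in spec.get("exact", []):
        entries.append((str(code), MatchMode.EXACT))
    for pref in spec.get("prefix", []):
        entries.append((str(pref), MatchMode.PREFIX))
    return CodeSet(name, tuple(entries))


def _as_date(v) -> dt.date:
    if isinstance(v, dt.date):
        return v
    return dt.date.fromisoformat(str(v))


def algorithm_config_from_dict(d: Mapping[str, Any],
                               index_date: dt.date | str) -> AlgorithmConfig:
    base = reference_defaults()["algorithm"]
    merged = {**base, **dict(d or {})}
    return AlgorithmConfig(
        index_date=_as_date(index_date),
        version=AlgorithmVersion(str(merged["version"]).upper()),
        amd_dx_codes=_code_set("amd_dx", merged["amd_dx_codes"]),
        wet_proc_codes=_code_set("anti_vegf_proc", merged["wet_proc_codes"]),
        wet_med_names=tuple(merged["wet_med_names"]),
        wet_same_date_dx=_code_set("amd_362_5_family",
                                   merged["wet_same_date_dx"]),
        min_amd_dx_dates=int(merged["min_amd_dx_dates"]),
        min_age_years=int(merged["min_age_years"]),
        control_lookback_years=float(merged["control_lookback_years"]),
        control_exclusion_codes=_code_set("control_exclusion",
                                          merged["control_exclusion_codes"]),
        require_ophthalmologist_dx=bool(merged["require_ophthalmologist_dx"]),
    )


def simulation_config_from_dict(d: Mapping[str, Any], seed: int,
                                n_patients: int | None = None
                                ) -> SimulationConfig:
    base = reference_defaults()["simulation"]
    merged = {**base, **dict(d or {})}
    return SimulationConfig(
        n_patients=int(n_patients if n_patients is not None
                       else merged["n_patients"]),
        seed=int(seed),
        index_date=_as_date(merged["index_date"]),
        age_distribution=tuple(float(x) for x in merged["age_distribution"]),
        prevalence={k: float(v) for k, v in merged["prevalence"].items()},
        p_miscode_amd=float(merged["p_miscode_amd"]),
        p_missed_second_visit=float(merged["p_missed_second_visit"]),
        p_injection_coded_same_date=float(
            merged["p_injection_coded_same_date"]),
        visit_rate=float(merged["visit_rate"]),
        p_specialty_other=float(merged["p_specialty_other"]),
    )


def association_config_from_dict(d: Mapping[str, Any]) -> AssociationConfig:
    base = reference_defaults()["association"]
    merged = {**base, **dict(d or {})}
    return AssociationConfig(
        covariates=tuple(merged["covariates"]),
        alpha=float(merged["alpha"]),
        m_tests=int(merged["m_tests"]),
        method=str(merged["method"]),
    )
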