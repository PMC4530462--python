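"""End-to-end pipeline orchestration and run manifests.

``run_pipeline`` chains simulate -> phenotype -> validate -> associate on
a synthetic cohort: the phenotyper labels the simulated EMR, labels are
validated against the planted truth, and genotypes with a planted allelic
odds ratio are simulated for the labeled cases/controls and tested for
association.  Every run writes its outputs plus a JSON manifest (command,
config snapshot, seeds, file digests, tool version) into a fresh run
directory; inputs are never mutated.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .association import (
    pool_and_associate,
    results_frame,
    simulate_case_control_genotypes,
)
from .config import (
    algorithm_config_from_dict,
    association_config_from_dict,
    reference_defaults,
    simulation_config_from_dict,
)
from .genotypes import GenotypeDosageMatrix, write_tsv_dosages
from .phenotyper import Label, classify_cohort
from .synthetic_emr import simulate_cohort, truth_to_expert_labels, write_truth
from .emr_model import write_cohort
from .validation import (
    AlgoLabel,
    ExpertLabel,
    LabeledPair,
    table1_report,
)

__all__ = ["RunManifest", "PipelineError", "run_pipeline",
           "labels_vs_truth_pairs"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    command: str
    config: dict
    seeds: dict
    version: str = __version__
    started: str = ""
    finished: str = ""
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True,
                                   default=str))


def labels_vs_truth_pairs(labels: pd.DataFrame,
                          expert: dict[str, ExpertLabel]) -> list[LabeledPair]:
    """Algorithm-vs-gold pairs for every *classified* patient.

    UNCLASSIFIED patients are neither called positive nor negative by the
    algorithm and are not chart-reviewable bins, so they are excluded —
    mirroring a review that samples only the algorithm's output classes.
    """
    pairs = []
    for r in labels.itertuples(index=False):
        if r.label == Label.UNCLASSIFIED.value:
            continue
        pairs.append(LabeledPair(r.patient_id, AlgoLabel(r.label),
                                 expert[r.patient_id]))
    return pairs


def run_pipeline(config_bundle: dict, seed: int, out_dir: str | Path,
                 n_patients: int | None = None) -> dict[str, Any]:
    """Run all stages; returns a summary dict. Outputs go to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    defaults = reference_defaults()
    bundle = {**defaults, **(config_bundle or {})}
    manifest = RunManifest(
        command="run", config=bundle,
        seeds={"seed": seed},
        started=dt.datetime.now(dt.timezone.utc).isoformat(),
    )

    # -- stage 1: simulate EMR cohort -----------------------------------
    try:
        sim_cfg = simulation_config_from_dict(bundle.get("simulation", {}),
                                              seed=seed,
                                              n_patients=n_patients)
        cohort, truths = simulate_cohort(sim_cfg)
        write_cohort(cohort, out / "patients.csv", out / "events.csv")
        write_truth(truths, out / "truth.csv")
    except Exception as exc:  # noqa: BLE001 - re-tag with stage
        raise PipelineError("simulate-emr", str(exc)) from exc

    # -- stage 2: phenotype ----------------------------------------------
    try:
        algo_cfg = algorithm_config_from_dict(
            bundle.get("algorithm", {}), index_date=sim_cfg.index_date)
        labels, counts = classify_cohort(cohort, algo_cfg)
        labels.to_csv(out / "labels.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("phenotype", str(exc)) from exc

    # -- stage 3: validate against planted truth -------------------------
    try:
        expert = truth_to_expert_labels(truths)
        pairs = labels_vs_truth_pairs(labels, expert)
        report = table1_report(pairs)
        (out / "validation_report.json").write_text(
            json.dumps(report.to_dict(), indent=2))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("validate", str(exc)) from exc

    # -- stage 4: simulate genotypes for labeled samples + associate -----
    try:
        n_cases = counts[Label.WET_AMD.value] + counts[Label.DRY_AMD.value]
        n_controls = counts[Label.CONTROL.value]
        if n_cases < 2 or n_controls < 2:
            raise ValueError(
                f"too few labeled samples for association "
                f"({n_cases} cases, {n_controls} controls)")
        gcfg = bundle.get("genotype_simulation", {})
        matrix, pheno = simulate_case_control_genotypes(
            n_cases=n_cases, n_controls=n_controls,
            raf_population=float(gcfg.get("raf_population", 0.363)),
            or_per_allele=float(gcfg.get("or_per_allele", 2.43)),
            prevalence=float(gcfg.get("prevalence", 0.10)),
            seed=seed + 1, snp_id="rs1061170", risk_allele="C")
        # split into two disjoint halves to exercise the pooling path
        half = matrix.dosages.index[::2], matrix.dosages.index[1::2]
        imputed = GenotypeDosageMatrix(matrix.dosages.loc[half[0]],
                                       dict(matrix.risk_allele))
        genotyped = GenotypeDosageMatrix(matrix.dosages.loc[half[1]],
                                         dict(matrix.risk_allele))
        assoc_cfg = association_config_from_dict(bundle.get("association", {}))
        results = pool_and_associate(imputed, genotyped, pheno, assoc_cfg)
        rf = results_frame(results)
        rf.to_csv(out / "association_results.tsv", sep="\t", index=False)
        write_tsv_dosages(matrix, out / "dosages.tsv", out / "risk_alleles.tsv")
        pheno.to_csv(out / "pheno.csv", index=False)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("associate", str(exc)) from exc

    manifest.finished = dt.datetime.now(dt.timezone.utc).isoformat()
    manifest.outputs = {
        p.name: _digest(p) for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest.write(out / "manifest.json")
    return {
        "counts": counts,
        "validation": report.to_dict(),
        "association": rf.to_dict(orient="records"),
        "manifest": manifest.__dict__,
    }
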