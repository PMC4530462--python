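"""Chart-review validation metrics for the phenotyping algorithm.

The algorithm's labels are compared against expert chart review (the gold
standard) as a 3x3 cross-tabulation of algorithm label (DRY_AMD, WET_AMD,
CONTROL) against expert label (DRY_AMD, WET_AMD, NOT_AMD).  From it we
compute, for a chosen positive class,

    PPV = TP / (TP + FP)      NPV = TN / (TN + FN)      FNR = FN / (FN + TP)

as exact rationals.  The standard report carries three rows: *overall AMD*
(positive = any AMD on both axes), *dry AMD* and *wet AMD* (subtype called
vs subtype confirmed, with "not called X" — the other subtype plus controls
— counted as test-negative).  Zero-denominator metrics are reported as
explicitly undefined, never silently 0 or 1.

Two reconstructed review fixtures are shipped as code:
``hundred_chart_review()`` (the 30 dry / 30 wet / 40 control revalidation)
and ``pilot_twenty_chart_review()`` (the 20-chart pilot; accuracy only).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlgoLabel",
    "ExpertLabel",
    "LabeledPair",
    "ConfusionMatrix",
    "Metric",
    "BinaryMetrics",
    "ValidationReport",
    "confusion_matrix",
    "binary_metrics",
    "table1_report",
    "read_pairs",
    "write_pairs",
    "hundred_chart_review",
    "pilot_twenty_chart_review",
]


class AlgoLabel(str, enum.Enum):
    DRY_AMD = "DRY_AMD"
    WET_AMD = "WET_AMD"
    CONTROL = "CONTROL"


class ExpertLabel(str, enum.Enum):
    DRY_AMD = "DRY_AMD"
    WET_AMD = "WET_AMD"
    NOT_AMD = "NOT_AMD"


@dataclass(frozen=True)
class LabeledPair:
    chart_id: str
    algorithm_label: AlgoLabel
    expert_label: ExpertLabel


_ALGO_ORDER = [AlgoLabel.DRY_AMD, AlgoLabel.WET_AMD, AlgoLabel.CONTROL]
_EXPERT_ORDER = [ExpertLabel.DRY_AMD, ExpertLabel.WET_AMD, ExpertLabel.NOT_AMD]


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 counts indexed (algorithm_label, expert_label)."""

    counts: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (3, 3) or (arr < 0).any():
            raise ValueError("counts must be a 3x3 non-negative table")

    @property
    def total(self) -> int:
        return int(np.asarray(self.counts).sum())

    def cell(self, algo: AlgoLabel, expert: ExpertLabel) -> int:
        return self.counts[_ALGO_ORDER.index(algo)][_EXPERT_ORDER.index(expert)]

    def row_sums(self) -> dict[AlgoLabel, int]:
        return {a: int(sum(self.counts[i])) for i, a in enumerate(_ALGO_ORDER)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.asarray(self.counts),
            index=[a.value for a in _ALGO_ORDER],
            columns=[e.value for e in _EXPERT_ORDER],
        )


def confusion_matrix(pairs: Iterable[LabeledPair]) -> ConfusionMatrix:
    arr = np.zeros((3, 3), dtype=int)
    for p in pairs:
        arr[_ALGO_ORDER.index(AlgoLabel(p.algorithm_label)),
            _EXPERT_ORDER.index(ExpertLabel(p.expert_label))] += 1
    return ConfusionMatrix(tuple(tuple(int(x) for x in row) for row in arr))


@dataclass(frozen=True)
class Metric:
    """An exact rational proportion, or an explicit undefined marker."""

    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def value(self) -> float:
        if not self.defined:
            return float("nan")
        return self.numerator / self.denominator

    @property
    def fraction(self) -> Fraction | None:
        return Fraction(self.numerator, self.denominator) if self.defined else None

    def __format__(self, spec: str) -> str:
        return "undefined" if not self.defined else format(self.value, spec)


@dataclass(frozen=True)
class BinaryMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    ppv: Metric
    npv: Metric
    fnr: Metric


def binary_metrics(cm: ConfusionMatrix,
                   positive_algorithm_labels: set[AlgoLabel],
                   positive_expert_labels: set[ExpertLabel]) -> BinaryMetrics:
    """Collapse the 3x3 table to 2x2 for the given positive sets."""
    if not positive_algorithm_labels or not positive_expert_labels:
        raise ValueError("positive label sets must be non-empty")
    tp = fp = tn = fn = 0
    for a in _ALGO_ORDER:
        for e in _EXPERT_ORDER:
            n = cm.cell(a, e)
            test_pos = a in positive_algorithm_labels
            truth_pos = e in positive_expert_labels
            if test_pos and truth_pos:
                tp += n
            elif test_pos:
                fp += n
            elif truth_pos:
                fn += n
            else:
                tn += n
    return BinaryMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        ppv=Metric(tp, tp + fp),
        npv=Metric(tn, tn + fn),
        fnr=Metric(fn, fn + tp),
    )


@dataclass(frozen=True)
class ValidationReport:
    overall_amd: BinaryMetrics
    dry_amd: BinaryMetrics
    wet_amd: BinaryMetrics
    overall_accuracy: Metric       # AMD-vs-control agreement
    three_class_agreement: Metric  # exact subtype-level agreement
    n_pairs: int

    def rows(self) -> pd.DataFrame:
        recs = []
        for name, m in [("overall_AMD", self.overall_amd),
                        ("dry_AMD", self.dry_amd),
                        ("wet_AMD", self.wet_amd)]:
            recs.append({
                "classification": name,
                "ppv": m.ppv.value, "npv": m.npv.value, "fnr": m.fnr.value,
                "ppv_fraction": f"{m.ppv.numerator}/{m.ppv.denominator}",
                "npv_fraction": f"{m.npv.numerator}/{m.npv.denominator}",
                "fnr_fraction": f"{m.fnr.numerator}/{m.fnr.denominator}",
            })
        return pd.DataFrame(recs)

    def to_dict(self) -> dict:
        def _m(m: Metric) -> dict:
            return {"value": m.value if m.defined else None,
                    "fraction": f"{m.numerator}/{m.denominator}",
                    "defined": m.defined}

        out: dict = {"n_pairs": self.n_pairs,
                     "overall_accuracy": _m(self.overall_accuracy),
                     "three_class_agreement": _m(self.three_class_agreement)}
        for name, bm in [("overall_AMD", self.overall_amd),
                         ("dry_AMD", self.dry_amd),
                         ("wet_AMD", self.wet_amd)]:
            out[name] = {"ppv": _m(bm.ppv), "npv": _m(bm.npv),
                         "fnr": _m(bm.fnr),
                         "tp": bm.tp, "fp": bm.fp, "tn": bm.tn, "fn": bm.fn}
        return out


def table1_report(pairs: Sequence[LabeledPair]) -> ValidationReport:
    """The standard three-row performance report plus accuracies."""
    cm = confusion_matrix(pairs)
    overall = binary_metrics(
        cm, {AlgoLabel.DRY_AMD, AlgoLabel.WET_AMD},
        {ExpertLabel.DRY_AMD, ExpertLabel.WET_AMD})
    dry = binary_metrics(cm, {AlgoLabel.DRY_AMD}, {ExpertLabel.DRY_AMD})
    wet = binary_metrics(cm, {AlgoLabel.WET_AMD}, {ExpertLabel.WET_AMD})
    trace = sum(cm.cell(a, e) for a, e in
                zip(_ALGO_ORDER, _EXPERT_ORDER))  # NOT_AMD aligns with CONTROL
    return ValidationReport(
        overall_amd=overall, dry_amd=dry, wet_amd=wet,
        overall_accuracy=Metric(overall.tp + overall.tn, cm.total),
        three_class_agreement=Metric(trace, cm.total),
        n_pairs=cm.total,
    )


def read_pairs(path: str | Path) -> list[LabeledPair]:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ("chart_id", "algorithm_label", "expert_label")
               if c not in df.columns]
    if missing:
        raise ValueError(f"pairs table {path} missing columns: {missing}")
    return [
        LabeledPair(str(r.chart_id), AlgoLabel(r.algorithm_label.strip()),
                    ExpertLabel(r.expert_label.strip()))
        for r in df.itertuples(index=False)
    ]


def write_pairs(pairs: Sequence[LabeledPair], path: str | Path) -> None:
    pd.DataFrame(
        [{"chart_id": p.chart_id,
          "algorithm_label": p.algorithm_label.value,
          "expert_label": p.expert_label.value} for p in pairs]
    ).to_csv(path, index=False)


def _bin(prefix: str, algo: AlgoLabel,
         expert_counts: list[tuple[ExpertLabel, int]]) -> list[LabeledPair]:
    pairs, i = [], 0
    for expert, n in expert_counts:
        for _ in range(n):
            i += 1
            pairs.append(LabeledPair(f"{prefix}{i:03d}", algo, expert))
    return pairs


def hundred_chart_review() -> list[LabeledPair]:
    """The reconstructed 100-chart revalidation review (synthetic stand-in).

    The review selected 30 dry-called, 30 wet-called and 40 control-called
    charts.  Expert outcomes per bin are the unique 3x3 assignment
    consistent with every reported figure (overall PPV 55/60, NPV 39/40,
    FNR 1/56; dry PPV 22/30; wet PPV 26/30; dry/wet FNR 3/25 and 5/31;
    94/100 AMD-vs-control accuracy):

    * dry bin: 22 confirmed dry, 4 actually wet, 4 not AMD;
    * wet bin: 26 confirmed wet, 3 actually dry, 1 not AMD;
    * control bin: 39 confirmed non-AMD, 1 missed wet pathology
      (a macular scar with polypoidal choroidal vasculopathy history).
    """
    return (
        _bin("D", AlgoLabel.DRY_AMD, [(ExpertLabel.DRY_AMD, 22),
                                      (ExpertLabel.WET_AMD, 4),
                                      (ExpertLabel.NOT_AMD, 4)])
        + _bin("W", AlgoLabel.WET_AMD, [(ExpertLabel.WET_AMD, 26),
                                        (ExpertLabel.DRY_AMD, 3),
                                        (ExpertLabel.NOT_AMD, 1)])
        + _bin("C", AlgoLabel.CONTROL, [(ExpertLabel.NOT_AMD, 39),
                                        (ExpertLabel.WET_AMD, 1)])
    )


def pilot_twenty_chart_review() -> list[LabeledPair]:
    """The reconstructed 20-chart pilot review (synthetic stand-in).

    The pilot selected 10 suspected-dry and 10 suspected-wet charts; 9 of
    20 were correctly subtyped, the rest were mimicker diseases (pattern
    dystrophy, diabetic retinopathy, central serous chorioretinopathy in
    the dry bin; proliferative diabetic retinopathy, myopic lacquer crack,
    macular scar, retinopathy of prematurity, birdshot chorioretinopathy in
    the wet bin).  The dry/wet split of the 9 correct charts is not
    determined, so this fixture supports only the accuracy computation.
    """
    return (
        _bin("PD", AlgoLabel.DRY_AMD, [(ExpertLabel.DRY_AMD, 5),
                                       (ExpertLabel.NOT_AMD, 5)])
        + _bin("PW", AlgoLabel.WET_AMD, [(ExpertLabel.WET_AMD, 4),
                                         (ExpertLabel.NOT_AMD, 6)])
    )
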