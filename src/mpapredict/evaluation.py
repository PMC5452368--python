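"""Confusion-matrix statistics with exact binomial confidence intervals.

The positive class throughout is the *poor* response: sensitivity is the
fraction of actual poor responders predicted poor, specificity the
fraction of actual good responders predicted good.  Confidence intervals
are Clopper–Pearson exact intervals (inversion of the binomial tails via
beta quantiles).  A severity-stratified report tabulates one confusion
matrix and accuracy per stratum (mild, severe, most severe) plus the
overall row.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

from scipy import stats

from .ct_data import ResponseLabel, Severity

__all__ = [
    "ConfusionMatrix",
    "BinomialCI",
    "StratumResult",
    "StratifiedReport",
    "confusion_matrix",
    "sensitivity",
    "specificity",
    "accuracy",
    "clopper_pearson",
    "stratified_accuracy",
    "evaluation_report",
    "roc_auc",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 counts, predicted × actual, with *poor* as the positive class.

    ``tp``: predicted poor & actually poor; ``fp``: predicted poor &
    actually good; ``fn``: predicted good & actually poor; ``tn``:
    predicted good & actually good.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count {name}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def actual_poor(self) -> int:
        return self.tp + self.fn

    @property
    def actual_good(self) -> int:
        return self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


def confusion_matrix(
    predicted: Sequence[ResponseLabel], actual: Sequence[ResponseLabel]
) -> ConfusionMatrix:
    """Tally predicted vs actual labels into a 2×2 matrix."""
    if len(predicted) != len(actual):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(actual)} actuals"
        )
    if len(predicted) == 0:
        raise ValueError("cannot tabulate zero label pairs")
    tp = fp = fn = tn = 0
    for p, a in zip(predicted, actual):
        if p is ResponseLabel.POOR:
            if a is ResponseLabel.POOR:
                tp += 1
            else:
                fp += 1
        else:
            if a is ResponseLabel.POOR:
                fn += 1
            else:
                tn += 1
    return ConfusionMatrix(tp, fp, fn, tn)


def sensitivity(cm: ConfusionMatrix) -> float:
    """Fraction of actual poor responders predicted poor (tp / actual poor)."""
    if cm.actual_poor == 0:
        raise ZeroDivisionError("sensitivity undefined: no actual poor responders")
    return cm.tp / cm.actual_poor


def specificity(cm: ConfusionMatrix) -> float:
    """Fraction of actual good responders predicted good (tn / actual good)."""
    if cm.actual_good == 0:
        raise ZeroDivisionError("specificity undefined: no actual good responders")
    return cm.tn / cm.actual_good


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of patients whose prediction matched the actual response."""
    if cm.total == 0:
        raise ZeroDivisionError("accuracy undefined: empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


@dataclass(frozen=True)
class BinomialCI:
    """An exact binomial confidence interval for a proportion."""

    point: float
    lower: float
    upper: float
    level: float = 0.95
    method: str = "clopper_pearson"

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.point <= self.upper <= 1.0):
            raise ValueError(
                f"interval ordering violated: {self.lower} <= {self.point} <= {self.upper}"
            )


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> BinomialCI:
    """Clopper–Pearson exact interval for ``successes / trials``.

    Obtained by inverting the binomial tail probabilities, equivalently
    via beta quantiles: lower = Beta(α/2; s, n−s+1) (0 when s = 0) and
    upper = Beta(1−α/2; s+1, n−s) (1 when s = n).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not (0 <= successes <= trials):
        raise ValueError(f"successes {successes} outside [0, {trials}]")
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must lie in (0, 1)")
    alpha = 1.0 - level
    if successes == 0:
        lower = 0.0
    else:
        lower = float(stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    if successes == trials:
        upper = 1.0
    else:
        upper = float(stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return BinomialCI(point=successes / trials, lower=lower, upper=upper, level=level)


@dataclass(frozen=True)
class StratumResult:
    stratum: Optional[Severity]  # None = overall row
    matrix: ConfusionMatrix

    @property
    def accuracy(self) -> float:
        return accuracy(self.matrix)


@dataclass
class StratifiedReport:
    """Per-severity confusion matrices and accuracies plus an overall row."""

    strata: tuple[StratumResult, ...]
    overall: StratumResult

    def stratum(self, severity: Severity) -> StratumResult:
        for s in self.strata:
            if s.stratum is severity:
                return s
        raise KeyError(severity)


_STRATUM_ORDER = (Severity.MILD, Severity.SEVERE, Severity.MOST_SEVERE)


def stratified_accuracy(
    results: Sequence[tuple[ResponseLabel, ResponseLabel, Optional[Severity]]],
    patient_ids: Optional[Sequence[str]] = None,
) -> StratifiedReport:
    """Severity-stratified evaluation of (predicted, actual, severity) triples.

    Strata are ordered mild, severe, most severe; strata with no patients
    are omitted.  A missing severity raises, naming the patient if ids
    are supplied.
    """
    if len(results) == 0:
        raise ValueError("no results to stratify")
    for i, (_, _, sev) in enumerate(results):
        if sev is None:
            who = patient_ids[i] if patient_ids is not None else f"record #{i}"
            raise ValueError(f"missing severity for {who}")
    strata = []
    for sev in _STRATUM_ORDER:
        triples = [(p, a) for p, a, s in results if s is sev]
        if not triples:
            continue
        cm = confusion_matrix([p for p, _ in triples], [a for _, a in triples])
        strata.append(StratumResult(stratum=sev, matrix=cm))
    overall_cm = confusion_matrix([p for p, _, _ in results], [a for _, a, _ in results])
    return StratifiedReport(
        strata=tuple(strata), overall=StratumResult(stratum=None, matrix=overall_cm)
    )


def roc_auc(indices: Sequence[float], actual: Sequence[ResponseLabel]) -> float:
    """Optional diagnostic: AUC of the raw index for the poor class.

    ROC analysis is deliberately not part of the decision rule (the
    boundary is the training dummy mean); this exists for comparison
    only.
    """
    from sklearn.metrics import roc_auc_score

    y = [a.dummy for a in actual]
    return float(roc_auc_score(y, list(indices)))


def evaluation_report(
    report: StratifiedReport, level: float = 0.95
) -> dict:
    """Bundle confusion counts, accuracies (as % at 1 d.p.) and exact CIs.

    Sensitivity/specificity CIs (3 d.p.) are computed on the overall
    matrix only, matching how the headline numbers are usually quoted.
    """
    cm = report.overall.matrix
    sens = sensitivity(cm)
    spec = specificity(cm)
    sens_ci = clopper_pearson(cm.tp, cm.actual_poor, level)
    spec_ci = clopper_pearson(cm.tn, cm.actual_good, level)
    out = {
        "overall": {
            "counts": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
            "n": cm.total,
            "sensitivity_pct": round(100 * sens, 1),
            "specificity_pct": round(100 * spec, 1),
            "accuracy_pct": round(100 * accuracy(cm), 1),
            "sensitivity_ci": [round(sens_ci.lower, 3), round(sens_ci.upper, 3)],
            "specificity_ci": [round(spec_ci.lower, 3), round(spec_ci.upper, 3)],
            "ci_level": level,
        },
        "strata": {},
    }
    for s in report.strata:
        m = s.matrix
        out["strata"][s.stratum.value] = {
            "counts": {"tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn},
            "n": m.total,
            "accuracy_pct": round(100 * s.accuracy, 1),
        }
    return out


def write_report_csv(
    report: StratifiedReport, sink: Union[str, Path, IO[str]]
) -> None:
    """Export ``stratum,tp,fp,fn,tn,accuracy`` rows plus an overall row."""
    own = isinstance(sink, (str, Path))
    fh = open(sink, "w", encoding="utf-8", newline="") if own else sink
    try:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["stratum", "tp", "fp", "fn", "tn", "accuracy"])
        for s in report.strata:
            m = s.matrix
            writer.writerow(
                [s.stratum.value, m.tp, m.fp, m.fn, m.tn, repr(s.accuracy)]
            )
        m = report.overall.matrix
        writer.writerow(["overall", m.tp, m.fp, m.fn, m.tn, repr(report.overall.accuracy)])
    finally:
        if own:
            fh.close()


def write_report_json(report_dict: dict, sink: Union[str, Path, IO[str]]) -> None:
    own = isinstance(sink, (str, Path))
    fh = open(sink, "w", encoding="utf-8") if own else sink
    try:
        json.dump(report_dict, fh, indent=2)
        fh.write("\n")
    finally:
        if own:
            fh.close()
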