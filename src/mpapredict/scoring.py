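"""The prediction index and its boundary-value classification.

The prediction index of a patient is an affine function of the 16
fold-change values,

    index = intercept + sum_g coefficient[g] * fold[g],

trained so that good responders (dummy 0) score low and poor responders
(dummy 1) score high.  An index below the boundary value predicts a good
response; above it, a poor response.  The published coefficients exist in
two printed variants that differ only in the IFIT5 term (−1.43 in the
contribution table vs −1.44 in the operational formula); both are
registered and the formula-text variant is the default.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Optional, Sequence, Union

from .ct_data import Cohort, PANEL_GENES, ResponseLabel
from .ddct import FoldChangeProfile, cohort_fold_changes

__all__ = [
    "PredictionModel",
    "PredictionResult",
    "published_model",
    "predict_index",
    "classify",
    "score_cohort",
    "write_scores",
]

PUBLISHED_INTERCEPT = 0.84
PUBLISHED_BOUNDARY = 0.23

# Per-gene contributions as printed in the published contribution table.
_TABLE2_COEFFS: dict[str, float] = {
    "IRF7": 0.74,
    "IFIT1": -0.32,
    "IFIT5": -1.43,
    "OASL": -0.18,
    "CLC": 0.05,
    "GBP1": -0.84,
    "PSMB9": 0.38,
    "HERC5": 0.37,
    "CCR1": -0.91,
    "CD36": -0.84,
    "MS4A4A": 0.43,
    "BIRC4BP": 0.93,
    "PLSCR1": 0.72,
    "DEFA1/DEFA3": 0.01,
    "DEFA4": -0.02,
    "COL9A2": -0.06,
}
# The operational in-text formula differs only in IFIT5.
_FORMULA_TEXT_COEFFS = {**_TABLE2_COEFFS, "IFIT5": -1.44}

_VARIANTS = {
    "table2": ("published_table2", _TABLE2_COEFFS),
    "formula_text": ("published_formula_text", _FORMULA_TEXT_COEFFS),
}


@dataclass(frozen=True)
class PredictionModel:
    """Affine prediction index with a decision boundary."""

    intercept: float
    coefficients: Mapping[str, float]
    boundary: float
    provenance: str = "fitted"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.boundary):
            raise ValueError("boundary must be finite")
        object.__setattr__(self, "coefficients", dict(self.coefficients))

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def to_json(self, sink: Union[str, Path, IO[str], None] = None) -> str:
        payload = json.dumps(
            {
                "intercept": self.intercept,
                "boundary": self.boundary,
                "provenance": self.provenance,
                "degenerate": self.degenerate,
                "coefficients": dict(self.coefficients),
            },
            indent=2,
        )
        if sink is not None:
            if isinstance(sink, (str, Path)):
                Path(sink).write_text(payload + "\n", encoding="utf-8")
            else:
                sink.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source: Union[str, Path, IO[str]]) -> "PredictionModel":
        if isinstance(source, (str, Path)):
            data = json.loads(Path(source).read_text(encoding="utf-8"))
        else:
            data = json.load(source)
        return cls(
            intercept=float(data["intercept"]),
            coefficients={g: float(v) for g, v in data["coefficients"].items()},
            boundary=float(data["boundary"]),
            provenance=str(data.get("provenance", "fitted")),
            degenerate=bool(data.get("degenerate", False)),
        )


@dataclass(frozen=True)
class PredictionResult:
    patient_id: str
    index: float
    predicted: ResponseLabel


def published_model(variant: str = "formula_text") -> PredictionModel:
    """The published model: intercept 0.84, boundary 0.23, 16 coefficients.

    ``variant`` selects the coefficient source: ``"table2"`` (contribution
    table; IFIT5 = −1.43) or ``"formula_text"`` (operational formula;
    IFIT5 = −1.44, the default).
    """
    try:
        provenance, coeffs = _VARIANTS[variant]
    except KeyError:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of {sorted(_VARIANTS)}"
        ) from None
    return PredictionModel(
        intercept=PUBLISHED_INTERCEPT,
        coefficients=coeffs,
        boundary=PUBLISHED_BOUNDARY,
        provenance=provenance,
    )


def predict_index(
    model: PredictionModel, profile: Union[FoldChangeProfile, Mapping[str, float]]
) -> float:
    """Evaluate the prediction index on one fold-change profile."""
    fold = profile.fold if isinstance(profile, FoldChangeProfile) else profile
    total = model.intercept
    for gene, coef in model.coefficients.items():
        try:
            total += coef * fold[gene]
        except KeyError:
            pid = getattr(profile, "patient_id", "?")
            raise KeyError(
                f"profile of patient {pid!r} lacks fold change for model gene {gene!r}"
            ) from None
    return total


def classify(index: float, boundary: float, tie: str = "poor") -> ResponseLabel:
    """Boundary rule: index below the boundary predicts a good response.

    The published rule states only strict inequalities; at exact equality
    this classifier defaults to ``POOR`` — the conservative choice for a
    test meant to trigger closer follow-up — and ``tie="good"`` flips it.
    """
    if not math.isfinite(index):
        raise ValueError(f"prediction index must be finite, got {index!r}")
    if not math.isfinite(boundary):
        raise ValueError(f"boundary must be finite, got {boundary!r}")
    if tie not in ("poor", "good"):
        raise ValueError(f"unknown tie rule {tie!r}")
    if index < boundary:
        return ResponseLabel.GOOD
    if index > boundary:
        return ResponseLabel.POOR
    return ResponseLabel.POOR if tie == "poor" else ResponseLabel.GOOD


def score_cohort(
    cohort: Cohort,
    model: PredictionModel,
    tie: str = "poor",
) -> list[PredictionResult]:
    """Index and predicted label for every patient in the cohort."""
    results = []
    for profile in cohort_fold_changes(cohort):
        index = predict_index(model, profile)
        results.append(
            PredictionResult(
                patient_id=profile.patient_id,
                index=index,
                predicted=classify(index, model.boundary, tie=tie),
            )
        )
    return results


def write_scores(
    results: Sequence[PredictionResult], sink: Union[str, Path, IO[str]]
) -> None:
    """Export scoring output as CSV ``patient_id,index,predicted``."""
    own = isinstance(sink, (str, Path))
    fh = open(sink, "w", encoding="utf-8", newline="") if own else sink
    try:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["patient_id", "index", "predicted"])
        for r in results:
            writer.writerow([r.patient_id, repr(r.index), r.predicted.label])
    finally:
        if own:
            fh.close()
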