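"""Published validation-cohort outcomes, reconstructed as label triples.

The validation study printed its complete predicted-vs-actual outcome
counts, stratified by disease severity, for the 39-patient cohort.
Those counts are a complete input in themselves: expanding them to
per-patient (predicted, actual, severity) triples lets the evaluation
machinery recompute every headline statistic (sensitivity 6/7,
specificity 31/32, accuracies per stratum) from first principles.
"""

from __future__ import annotations

from .ct_data import ResponseLabel, Severity
from .evaluation import ConfusionMatrix

__all__ = [
    "PUBLISHED_STRATUM_COUNTS",
    "published_confusion_matrix",
    "published_validation_triples",
]

# Per-severity counts (tp, fp, fn, tn) with poor as positive class:
#   mild (n=17): 3 predicted-poor/actual-poor, 14 predicted-good/actual-good
#   severe (n=18): 2 tp, 1 fp, 15 tn
#   most severe (n=4): 1 tp, 1 fn, 2 tn
PUBLISHED_STRATUM_COUNTS: dict[Severity, ConfusionMatrix] = {
    Severity.MILD: ConfusionMatrix(tp=3, fp=0, fn=0, tn=14),
    Severity.SEVERE: ConfusionMatrix(tp=2, fp=1, fn=0, tn=15),
    Severity.MOST_SEVERE: ConfusionMatrix(tp=1, fp=0, fn=1, tn=2),
}


def published_confusion_matrix() -> ConfusionMatrix:
    """Overall 39-patient matrix: tp=6, fp=1, fn=1, tn=31."""
    total = ConfusionMatrix(0, 0, 0, 0)
    for cm in PUBLISHED_STRATUM_COUNTS.values():
        total = total + cm
    return total


def published_validation_triples() -> list[
    tuple[ResponseLabel, ResponseLabel, Severity]
]:
    """The 39 (predicted, actual, severity) triples behind the counts."""
    triples = []
    for sev, cm in PUBLISHED_STRATUM_COUNTS.items():
        triples += [(ResponseLabel.POOR, ResponseLabel.POOR, sev)] * cm.tp
        triples += [(ResponseLabel.POOR, ResponseLabel.GOOD, sev)] * cm.fp
        triples += [(ResponseLabel.GOOD, ResponseLabel.POOR, sev)] * cm.fn
        triples += [(ResponseLabel.GOOD, ResponseLabel.GOOD, sev)] * cm.tn
    return triples
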