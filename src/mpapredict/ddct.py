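"""Relative-quantification transform: ΔCt, ΔΔCt and 2^(−ΔΔCt) fold change.

For a target gene, ΔCt = Ct(target) − Ct(housekeeping) within one sample;
ΔΔCt = ΔCt(post) − ΔCt(pre) across the two timepoints; and the
post-treatment expression relative to pre-treatment is 2^(−ΔΔCt), under
the usual assumption of perfect (100%) amplification efficiency, i.e. a
doubling of product per PCR cycle.  A fold below 1 means the gene's
expression fell after treatment.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping, Optional, Sequence, Union

from .ct_data import Cohort, GenePanel, PatientRecord, Timepoint

__all__ = [
    "FoldChangeProfile",
    "delta_ct",
    "delta_delta_ct",
    "fold_change",
    "patient_fold_changes",
    "cohort_fold_changes",
    "write_fold_changes",
]


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


def delta_ct(ct_target: float, ct_housekeeping: float) -> float:
    """ΔCt in cycles: target Ct minus housekeeping Ct within one sample."""
    return _require_finite("ct_target", ct_target) - _require_finite(
        "ct_housekeeping", ct_housekeeping
    )


def delta_delta_ct(dct_post: float, dct_pre: float) -> float:
    """ΔΔCt in cycles: post-treatment ΔCt minus pre-treatment ΔCt."""
    return _require_finite("dct_post", dct_post) - _require_finite("dct_pre", dct_pre)


def fold_change(ddct: float, base: float = 2.0) -> float:
    """Relative post/pre expression ``base ** (−ΔΔCt)``.

    ``base`` defaults to 2 (exact doubling per cycle); a per-gene base
    could model imperfect amplification efficiency but 2 is used
    throughout this pipeline.
    """
    return base ** (-_require_finite("ddct", ddct))


@dataclass(frozen=True)
class FoldChangeProfile:
    """Per-patient mapping gene → 2^(−ΔΔCt); keys are the panel genes."""

    patient_id: str
    fold: Mapping[str, float]

    def __post_init__(self) -> None:
        for gene, value in self.fold.items():
            if not (math.isfinite(value) and value > 0):
                raise ValueError(
                    f"patient {self.patient_id!r}: fold change for {gene!r} "
                    f"must be a positive finite number, got {value!r}"
                )

    def __getitem__(self, gene: str) -> float:
        return self.fold[gene]

    def genes(self) -> tuple[str, ...]:
        return tuple(self.fold)


def patient_fold_changes(
    record: PatientRecord, panel: GenePanel, base: float = 2.0
) -> FoldChangeProfile:
    """Fold-change profile of one patient over a panel's predictor genes.

    Raises ``KeyError`` naming the patient and missing cell if any Ct
    value the transform needs is absent.
    """
    hk = panel.housekeeping_gene
    hk_pre = record.ct(hk, Timepoint.PRE)
    hk_post = record.ct(hk, Timepoint.POST)
    fold: dict[str, float] = {}
    for gene in panel.predictor_genes:
        dct_pre = delta_ct(record.ct(gene, Timepoint.PRE), hk_pre)
        dct_post = delta_ct(record.ct(gene, Timepoint.POST), hk_post)
        fold[gene] = fold_change(delta_delta_ct(dct_post, dct_pre), base=base)
    return FoldChangeProfile(patient_id=record.patient_id, fold=fold)


def cohort_fold_changes(
    cohort: Cohort, panel: Optional[GenePanel] = None, base: float = 2.0
) -> list[FoldChangeProfile]:
    """One fold-change profile per record, in cohort order.

    ``panel`` overrides the cohort's own panel, e.g. to transform decoy
    genes during selection experiments.
    """
    panel = panel or cohort.panel
    return [patient_fold_changes(rec, panel, base=base) for rec in cohort.records]


def write_fold_changes(
    profiles: Sequence[FoldChangeProfile],
    sink: Union[str, Path, IO[str]],
    genes: Optional[Sequence[str]] = None,
) -> None:
    """Export profiles as wide CSV ``patient_id,<gene1>,...``."""
    if genes is None:
        genes = profiles[0].genes() if profiles else ()
    own = isinstance(sink, (str, Path))
    fh = open(sink, "w", encoding="utf-8", newline="") if own else sink
    try:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["patient_id", *genes])
        for p in profiles:
            writer.writerow([p.patient_id, *(repr(p.fold[g]) for g in genes)])
    finally:
        if own:
            fh.close()
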