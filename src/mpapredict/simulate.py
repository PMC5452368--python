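"""Synthetic paired-timepoint qPCR cohorts.

The generator emulates the expression structure the prediction method
assumes: in good responders, treatment lowers the expression of the 13
down-regulated panel genes (ΔΔCt shifted by ``+effect_ddct`` cycles, so
fold < 1) and raises the 3 up-regulated genes (ΔΔCt shifted by
``−effect_ddct``); in poor responders no systematic shift occurs.  Decoy
genes — uninformative in both classes — are added so that 30-candidate
selection experiments can be built.  Noise is Gaussian on every Ct
*measurement* (the observable), so housekeeping noise propagates into
ΔCt the way it would on an instrument.  Everything is deterministic
given the seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Mapping, Optional, Sequence, Union

import numpy as np

from .ct_data import (
    Cohort,
    DOWN_GENES,
    GenePanel,
    HOUSEKEEPING_GENE,
    PatientRecord,
    ResponseLabel,
    Severity,
    Timepoint,
    UP_GENES,
    published_panel,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_training_validation_pair",
    "write_ground_truth",
]

# Class balances of the original study design: the 22-patient training
# cohort held 5 poor responders, the 39-patient validation cohort 7.
TRAINING_POOR_FRACTION = 5 / 22
VALIDATION_POOR_FRACTION = 7 / 39
# Validation severity mix: 17 mild, 18 severe, 4 most severe of 39.
SEVERITY_PROBS = (17 / 39, 18 / 39, 4 / 39)

_SEVERITIES = (Severity.MILD, Severity.SEVERE, Severity.MOST_SEVERE)


@dataclass
class SyntheticConfig:
    """Generative parameters of a synthetic cohort.

    ``effect_ddct`` is the mean |ΔΔCt| shift (cycles) that treatment
    induces on informative genes in good responders; ``ct_noise_sd`` is
    the Gaussian noise (cycles) added independently to every single Ct
    measurement, so an observed ΔΔCt carries noise of sd
    ``2 * ct_noise_sd`` (four measurements enter it).  Baseline
    expression levels (pre-treatment ΔCt) are drawn uniformly per
    patient and gene from ``baseline_dct_range``.
    """

    n_patients: int = 39
    poor_fraction: float = TRAINING_POOR_FRACTION
    down_genes: tuple[str, ...] = DOWN_GENES
    up_genes: tuple[str, ...] = UP_GENES
    effect_ddct: float = 1.5
    ct_noise_sd: float = 0.25
    baseline_dct_range: tuple[float, float] = (-2.0, 8.0)
    n_decoy_genes: int = 14
    severity_probs: tuple[float, float, float] = SEVERITY_PROBS
    seed: int = 0
    housekeeping_ct: float = 20.0
    # Optional per-gene |ΔΔCt| effects overriding effect_ddct.
    per_gene_effect: Optional[Mapping[str, float]] = None
    # Hook: fraction by which the effect shrinks per severity level
    # beyond mild (0 = severity does not modulate the effect; this is a
    # modeling convenience, not an observed mechanism).
    severity_attenuation: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not (0.0 <= self.poor_fraction <= 1.0):
            raise ValueError("poor_fraction must lie in [0, 1]")
        if self.ct_noise_sd <= 0:
            raise ValueError("ct_noise_sd must be > 0")
        if self.effect_ddct < 0:
            raise ValueError("effect_ddct must be >= 0")
        if self.n_decoy_genes < 0:
            raise ValueError("n_decoy_genes must be >= 0")
        probs = np.asarray(self.severity_probs, dtype=float)
        if probs.shape != (3,) or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("severity_probs must be 3 non-negative numbers summing to 1")
        lo, hi = self.baseline_dct_range
        if not lo < hi:
            raise ValueError("baseline_dct_range must be a non-empty interval")

    @property
    def informative_genes(self) -> tuple[str, ...]:
        return tuple(self.down_genes) + tuple(self.up_genes)

    @property
    def decoy_genes(self) -> tuple[str, ...]:
        return tuple(f"DECOY{i + 1:02d}" for i in range(self.n_decoy_genes))


@dataclass
class GroundTruth:
    """What the generator actually drew, keyed by patient id."""

    responses: dict[str, ResponseLabel]
    severities: dict[str, Severity]
    informative_genes: tuple[str, ...]
    decoy_genes: tuple[str, ...]

    @property
    def candidate_genes(self) -> tuple[str, ...]:
        """Candidate pool for selection experiments: informative + decoys."""
        return self.informative_genes + self.decoy_genes


def _signed_effect(config: SyntheticConfig, gene: str) -> float:
    """Mean ΔΔCt of a gene in good responders: positive for down-regulated
    genes (expression falls, fold < 1), negative for up-regulated ones."""
    if config.per_gene_effect is not None and gene in config.per_gene_effect:
        magnitude = float(config.per_gene_effect[gene])
    else:
        magnitude = config.effect_ddct
    if gene in config.down_genes:
        return magnitude
    if gene in config.up_genes:
        return -magnitude
    return 0.0


def _generate_records(
    config: SyntheticConfig,
    rng: np.random.Generator,
    patient_ids: Sequence[str],
    responses: Sequence[ResponseLabel],
) -> tuple[list[PatientRecord], GroundTruth]:
    genes = list(config.informative_genes) + list(config.decoy_genes)
    lo, hi = config.baseline_dct_range
    severities = rng.choice(3, size=len(patient_ids), p=np.asarray(config.severity_probs))
    records: list[PatientRecord] = []
    truth_resp: dict[str, ResponseLabel] = {}
    truth_sev: dict[str, Severity] = {}
    for pid, resp, sev_idx in zip(patient_ids, responses, severities):
        severity = _SEVERITIES[int(sev_idx)]
        attenuation = max(0.0, 1.0 - config.severity_attenuation * int(sev_idx))
        rec = PatientRecord(patient_id=pid, severity=severity, actual_response=resp)
        # True (noise-free) housekeeping level at each timepoint.
        hk_true = config.housekeeping_ct
        noise = lambda: rng.normal(0.0, config.ct_noise_sd)
        rec.set_ct(HOUSEKEEPING_GENE, Timepoint.PRE, hk_true + noise())
        rec.set_ct(HOUSEKEEPING_GENE, Timepoint.POST, hk_true + noise())
        for gene in genes:
            dct_pre = rng.uniform(lo, hi)
            ddct = (
                _signed_effect(config, gene) * attenuation
                if resp is ResponseLabel.GOOD
                else 0.0
            )
            rec.set_ct(gene, Timepoint.PRE, hk_true + dct_pre + noise())
            rec.set_ct(gene, Timepoint.POST, hk_true + dct_pre + ddct + noise())
        records.append(rec)
        truth_resp[pid] = resp
        truth_sev[pid] = severity
    truth = GroundTruth(
        responses=truth_resp,
        severities=truth_sev,
        informative_genes=config.informative_genes,
        decoy_genes=config.decoy_genes,
    )
    return records, truth


def generate_cohort(
    config: SyntheticConfig, id_prefix: str = "P"
) -> tuple[Cohort, GroundTruth]:
    """Draw one cohort: responses Bernoulli(poor_fraction), severities
    categorical, Ct values per the generative model above."""
    rng = np.random.default_rng(config.seed)
    patient_ids = [f"{id_prefix}{i + 1:04d}" for i in range(config.n_patients)]
    responses = [
        ResponseLabel.POOR if rng.random() < config.poor_fraction else ResponseLabel.GOOD
        for _ in patient_ids
    ]
    records, truth = _generate_records(config, rng, patient_ids, responses)
    return Cohort(records=tuple(records), panel=published_panel()), truth


def _exact_count_responses(n: int, poor_fraction: float) -> list[ResponseLabel]:
    n_poor = round(n * poor_fraction)
    return [ResponseLabel.POOR] * n_poor + [ResponseLabel.GOOD] * (n - n_poor)


def generate_training_validation_pair(
    config: SyntheticConfig,
    n_train: int = 22,
    n_validation: int = 39,
    train_poor_fraction: float = TRAINING_POOR_FRACTION,
    validation_poor_fraction: float = VALIDATION_POOR_FRACTION,
) -> tuple[tuple[Cohort, GroundTruth], tuple[Cohort, GroundTruth]]:
    """Two disjoint cohorts mirroring the original design: a training
    cohort (default 22 patients, 17 good / 5 poor) and a validation
    cohort (default 39 patients, 32 good / 7 poor), drawn from the same
    generative parameters.  Class counts are exact (rounded from the
    fractions), not Bernoulli."""
    rng = np.random.default_rng(config.seed)
    train_ids = [f"T{i + 1:04d}" for i in range(n_train)]
    val_ids = [f"V{i + 1:04d}" for i in range(n_validation)]
    train_resp = _exact_count_responses(n_train, train_poor_fraction)
    val_resp = _exact_count_responses(n_validation, validation_poor_fraction)
    train_records, train_truth = _generate_records(config, rng, train_ids, train_resp)
    val_records, val_truth = _generate_records(config, rng, val_ids, val_resp)
    panel = published_panel()
    return (
        (Cohort(records=tuple(train_records), panel=panel), train_truth),
        (Cohort(records=tuple(val_records), panel=panel), val_truth),
    )


def write_ground_truth(truth: GroundTruth, sink: Union[str, Path, IO[str]]) -> None:
    """Export ground truth as CSV ``patient_id,true_response,severity``."""
    own = isinstance(sink, (str, Path))
    fh = open(sink, "w", encoding="utf-8", newline="") if own else sink
    try:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["patient_id", "true_response", "severity"])
        for pid, resp in truth.responses.items():
            writer.writerow([pid, resp.label, truth.severities[pid].value])
    finally:
        if own:
            fh.close()
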