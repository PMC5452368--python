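"""Cohorts of paired-timepoint qPCR Ct measurements.

A cohort holds one :class:`PatientRecord` per patient, each carrying raw
Ct values (the PCR cycle number at which the amplification product crosses
the detection threshold; lower Ct means higher expression) for every gene
of a :class:`GenePanel` at two timepoints: before remission-induction
therapy and one week after it begins.  The module also registers the
published 16-gene predictor panel (housekeeping gene: beta-actin) and
provides CSV readers/writers in two layouts plus a validation pass that
decides whether a record is scorable.
"""

from __future__ import annotations

import csv
import enum
import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "Timepoint",
    "Severity",
    "ResponseLabel",
    "GenePanel",
    "PatientRecord",
    "Cohort",
    "ValidationIssue",
    "ValidationReport",
    "PANEL_GENES",
    "DOWN_GENES",
    "UP_GENES",
    "HOUSEKEEPING_GENE",
    "normalize_gene_symbol",
    "published_panel",
    "read_ct_table",
    "write_ct_table",
    "validate_cohort",
]


class Timepoint(str, enum.Enum):
    """Sampling timepoint: before therapy, or 1 week after it begins."""

    PRE = "pre"
    POST = "post"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Severity(str, enum.Enum):
    """Clinical severity stratum of microscopic polyangiitis."""

    MILD = "mild"
    SEVERE = "severe"
    MOST_SEVERE = "most_severe"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ResponseLabel(enum.Enum):
    """Response to remission-induction therapy.

    ``GOOD`` (persistent remission) is dummy-coded 0, ``POOR`` (no
    remission, or relapse after remission) is dummy-coded 1.
    """

    GOOD = 0
    POOR = 1

    @property
    def dummy(self) -> int:
        return self.value

    @classmethod
    def from_label(cls, label: str) -> "ResponseLabel":
        key = label.strip().lower()
        if key == "good":
            return cls.GOOD
        if key == "poor":
            return cls.POOR
        raise ValueError(f"unknown response label: {label!r}")

    @property
    def label(self) -> str:
        return self.name.lower()


# The published predictor panel, in the order the prediction formula lists
# its terms.  The first 13 genes fall after treatment in good responders,
# the last 3 rise.
PANEL_GENES: tuple[str, ...] = (
    "IRF7",
    "IFIT1",
    "IFIT5",
    "OASL",
    "CLC",
    "GBP1",
    "PSMB9",
    "HERC5",
    "CCR1",
    "CD36",
    "MS4A4A",
    "BIRC4BP",
    "PLSCR1",
    "DEFA1/DEFA3",
    "DEFA4",
    "COL9A2",
)
DOWN_GENES: tuple[str, ...] = PANEL_GENES[:13]
UP_GENES: tuple[str, ...] = PANEL_GENES[13:]
HOUSEKEEPING_GENE = "ACTB"

# Spelling variants seen in the literature for panel members.  Symbols are
# matched case-insensitively after whitespace stripping; these aliases are
# applied afterwards.
_GENE_ALIASES: dict[str, str] = {
    "GBP-1": "GBP1",
    "DEFA/DEFA3": "DEFA1/DEFA3",
    "DEFA1": "DEFA1/DEFA3",
    "BETA-ACTIN": HOUSEKEEPING_GENE,
    "B-ACTIN": HOUSEKEEPING_GENE,
    "β-ACTIN": HOUSEKEEPING_GENE,
}


def normalize_gene_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol: stripped, upper-cased, de-aliased."""
    s = symbol.strip().upper()
    return _GENE_ALIASES.get(s, s)


@dataclass(frozen=True)
class GenePanel:
    """An ordered predictor gene list plus its housekeeping gene."""

    predictor_genes: tuple[str, ...]
    housekeeping_gene: str

    def __post_init__(self) -> None:
        genes = tuple(normalize_gene_symbol(g) for g in self.predictor_genes)
        hk = normalize_gene_symbol(self.housekeeping_gene)
        if any(not g for g in genes):
            raise ValueError("empty predictor gene symbol")
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate predictor gene symbols")
        if hk in genes:
            raise ValueError("housekeeping gene must not be a predictor")
        object.__setattr__(self, "predictor_genes", genes)
        object.__setattr__(self, "housekeeping_gene", hk)

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.predictor_genes + (self.housekeeping_gene,)

    def __len__(self) -> int:
        return len(self.predictor_genes)


def published_panel() -> GenePanel:
    """The published 16-gene predictor panel with beta-actin housekeeping."""
    return GenePanel(predictor_genes=PANEL_GENES, housekeeping_gene=HOUSEKEEPING_GENE)


@dataclass
class PatientRecord:
    """One patient's Ct measurements at both timepoints.

    ``ct_values`` maps ``(gene symbol, Timepoint)`` to a Ct value in PCR
    cycles.  Severity and the actual (observed) response are optional:
    scoring needs neither, evaluation needs the response and, for the
    stratified report, the severity.
    """

    patient_id: str
    ct_values: dict[tuple[str, Timepoint], float] = field(default_factory=dict)
    severity: Optional[Severity] = None
    actual_response: Optional[ResponseLabel] = None

    def ct(self, gene: str, timepoint: Timepoint) -> float:
        key = (normalize_gene_symbol(gene), Timepoint(timepoint))
        try:
            return self.ct_values[key]
        except KeyError:
            raise KeyError(
                f"patient {self.patient_id!r}: no Ct for gene {key[0]!r} at {key[1].value!r}"
            ) from None

    def has_ct(self, gene: str, timepoint: Timepoint) -> bool:
        return (normalize_gene_symbol(gene), Timepoint(timepoint)) in self.ct_values

    def set_ct(self, gene: str, timepoint: Timepoint, value: float) -> None:
        self.ct_values[(normalize_gene_symbol(gene), Timepoint(timepoint))] = float(value)

    def genes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for gene, _ in self.ct_values:
            seen.setdefault(gene)
        return tuple(seen)


@dataclass
class Cohort:
    """A sequence of patient records sharing one gene panel."""

    records: tuple[PatientRecord, ...]
    panel: GenePanel

    def __post_init__(self) -> None:
        self.records = tuple(self.records)
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_ids in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, patient_id: str) -> PatientRecord:
        for r in self.records:
            if r.patient_id == patient_id:
                return r
        raise KeyError(patient_id)


@dataclass(frozen=True)
class ValidationIssue:
    patient_id: str
    message: str
    level: str = "error"  # "error" blocks scoring; "warning" does not


@dataclass
class ValidationReport:
    """Per-patient issues found by :func:`validate_cohort`."""

    issues: tuple[ValidationIssue, ...]

    @property
    def errors(self) -> tuple[ValidationIssue, ...]:
        return tuple(i for i in self.issues if i.level == "error")

    @property
    def ok(self) -> bool:
        return not self.errors

    def issues_for(self, patient_id: str) -> tuple[ValidationIssue, ...]:
        return tuple(i for i in self.issues if i.patient_id == patient_id)

    def scorable_ids(self, cohort: "Cohort") -> tuple[str, ...]:
        bad = {i.patient_id for i in self.errors}
        return tuple(r.patient_id for r in cohort.records if r.patient_id not in bad)


def validate_cohort(
    cohort: Cohort,
    ct_window: tuple[float, float] = (0.0, 45.0),
    require_response: bool = False,
    require_severity: bool = False,
) -> ValidationReport:
    """Report missing Ct cells, implausible Ct values and missing metadata.

    Pure reporting: the cohort is never mutated.  A record with zero
    issues is scorable against the cohort's panel.  The default Ct
    plausibility window of (0, 45] cycles is a sanity screen, not a rule
    of the assay.
    """
    lo, hi = ct_window
    issues: list[ValidationIssue] = []
    panel_genes = set(cohort.panel.all_genes)
    for rec in cohort.records:
        for gene in cohort.panel.all_genes:
            for tp in Timepoint:
                if not rec.has_ct(gene, tp):
                    kind = (
                        "housekeeping"
                        if gene == cohort.panel.housekeeping_gene
                        else "panel"
                    )
                    issues.append(
                        ValidationIssue(
                            rec.patient_id,
                            f"missing {kind} Ct: gene {gene!r} at timepoint {tp.value!r}",
                        )
                    )
        for (gene, tp), value in rec.ct_values.items():
            if not math.isfinite(value):
                issues.append(
                    ValidationIssue(
                        rec.patient_id,
                        f"non-finite Ct for gene {gene!r} at {tp.value!r}",
                    )
                )
            elif not (lo < value <= hi):
                issues.append(
                    ValidationIssue(
                        rec.patient_id,
                        f"Ct outside plausibility window ({lo}, {hi}]: "
                        f"gene {gene!r} at {tp.value!r} has Ct {value}",
                    )
                )
        for gene in sorted({g for g, _ in rec.ct_values} - panel_genes):
            issues.append(
                ValidationIssue(
                    rec.patient_id,
                    f"gene {gene!r} not in the cohort panel (retained, ignored by scoring)",
                    level="warning",
                )
            )
        if require_response and rec.actual_response is None:
            issues.append(ValidationIssue(rec.patient_id, "missing actual_response"))
        if require_severity and rec.severity is None:
            issues.append(ValidationIssue(rec.patient_id, "missing severity"))
    return ValidationReport(issues=tuple(issues))


# ---------------------------------------------------------------------------
# CSV I/O
#
# Long layout:  patient_id,severity,actual_response,gene,timepoint,ct
# Wide layout:  patient_id,severity,actual_response,<gene>__pre,<gene>__post,...
# ---------------------------------------------------------------------------

_LONG_HEADER = ["patient_id", "severity", "actual_response", "gene", "timepoint", "ct"]
_NA_STRINGS = {"", "na", "nan", "none"}


def _parse_severity(text: str, where: str) -> Optional[Severity]:
    if text.strip().lower() in _NA_STRINGS:
        return None
    try:
        return Severity(text.strip().lower())
    except ValueError:
        raise ValueError(f"{where}: unknown severity {text!r}") from None


def _parse_response(text: str, where: str) -> Optional[ResponseLabel]:
    if text.strip().lower() in _NA_STRINGS:
        return None
    try:
        return ResponseLabel.from_label(text)
    except ValueError:
        raise ValueError(f"{where}: unknown actual_response {text!r}") from None


def _parse_ct(text: str, where: str) -> float:
    try:
        value = float(text)
    except (TypeError, ValueError):
        raise ValueError(f"{where}: non-numeric Ct value {text!r}") from None
    return value


def _open_source(source: Union[str, Path, IO[str]]):
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline=""), True
    return source, False


def _open_sink(sink: Union[str, Path, IO[str]]):
    if isinstance(sink, (str, Path)):
        return open(sink, "w", encoding="utf-8", newline=""), True
    return sink, False


def read_ct_table(
    source: Union[str, Path, IO[str]],
    layout: str = "long",
    panel: Optional[GenePanel] = None,
    replicates: str = "error",
) -> Cohort:
    """Read a cohort from CSV.

    Parameters
    ----------
    source
        Path or open text stream.
    layout
        ``"long"`` (one row per measurement) or ``"wide"`` (one row per
        patient with ``<gene>__pre`` / ``<gene>__post`` columns).
    panel
        Panel to attach to the cohort; defaults to the published panel.
    replicates
        Long layout only.  ``"error"`` (default) rejects duplicate
        (patient, gene, timepoint) rows; ``"mean"`` averages them.
    """
    if layout not in ("long", "wide"):
        raise ValueError(f"unknown layout {layout!r}")
    if replicates not in ("error", "mean"):
        raise ValueError(f"unknown replicates policy {replicates!r}")
    panel = panel or published_panel()
    fh, close = _open_source(source)
    try:
        if layout == "long":
            return _read_long(fh, panel, replicates)
        return _read_wide(fh, panel)
    finally:
        if close:
            fh.close()


def _read_long(fh: IO[str], panel: GenePanel, replicates: str) -> Cohort:
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except StopIteration:
        raise ValueError("empty CSV: missing header") from None
    if [h.strip() for h in header] != _LONG_HEADER:
        raise ValueError(
            f"line 1: bad long-layout header {header!r}, expected {_LONG_HEADER!r}"
        )
    records: dict[str, PatientRecord] = {}
    counts: dict[tuple[str, str, Timepoint], int] = {}
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(_LONG_HEADER):
            raise ValueError(f"line {lineno}: expected {len(_LONG_HEADER)} fields, got {len(row)}")
        pid, sev, resp, gene, tp_text, ct_text = row
        where = f"line {lineno} (patient {pid!r}, gene {gene!r})"
        try:
            tp = Timepoint(tp_text.strip().lower())
        except ValueError:
            raise ValueError(f"{where}: unknown timepoint {tp_text!r}") from None
        gene = normalize_gene_symbol(gene)
        ct = _parse_ct(ct_text, where)
        rec = records.get(pid)
        if rec is None:
            rec = records[pid] = PatientRecord(
                patient_id=pid,
                severity=_parse_severity(sev, where),
                actual_response=_parse_response(resp, where),
            )
        key = (pid, gene, tp)
        n_seen = counts.get(key, 0)
        if n_seen and replicates == "error":
            raise ValueError(
                f"{where}: duplicate Ct for (patient, gene, timepoint) "
                f"({pid!r}, {gene!r}, {tp.value!r}); pass replicates='mean' to average"
            )
        if n_seen:  # running mean over technical replicates
            prev = rec.ct_values[(gene, tp)]
            rec.ct_values[(gene, tp)] = (prev * n_seen + ct) / (n_seen + 1)
        else:
            rec.ct_values[(gene, tp)] = ct
        counts[key] = n_seen + 1
    return Cohort(records=tuple(records.values()), panel=panel)


def _read_wide(fh: IO[str], panel: GenePanel) -> Cohort:
    reader = csv.reader(fh)
    try:
        header = [h.strip() for h in next(reader)]
    except StopIteration:
        raise ValueError("empty CSV: missing header") from None
    if header[:3] != ["patient_id", "severity", "actual_response"]:
        raise ValueError(
            f"line 1: wide layout must start with patient_id,severity,actual_response, got {header[:3]!r}"
        )
    gene_cols: list[tuple[str, Timepoint]] = []
    for col in header[3:]:
        if col.endswith("__pre"):
            gene_cols.append((normalize_gene_symbol(col[:-5]), Timepoint.PRE))
        elif col.endswith("__post"):
            gene_cols.append((normalize_gene_symbol(col[:-6]), Timepoint.POST))
        else:
            raise ValueError(f"line 1: column {col!r} lacks a __pre/__post suffix")
    records = []
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(header):
            raise ValueError(f"line {lineno}: expected {len(header)} fields, got {len(row)}")
        pid = row[0]
        where = f"line {lineno} (patient {pid!r})"
        rec = PatientRecord(
            patient_id=pid,
            severity=_parse_severity(row[1], where),
            actual_response=_parse_response(row[2], where),
        )
        for (gene, tp), cell in zip(gene_cols, row[3:]):
            if cell.strip().lower() in _NA_STRINGS:
                continue  # missing cell: record stays unscorable, validation reports it
            rec.ct_values[(gene, tp)] = _parse_ct(cell, f"{where}, column {gene}__{tp.value}")
        records.append(rec)
    return Cohort(records=tuple(records), panel=panel)


def write_ct_table(
    cohort: Cohort,
    sink: Union[str, Path, IO[str]],
    layout: str = "long",
) -> None:
    """Write a cohort to CSV; inverse of :func:`read_ct_table`."""
    if layout not in ("long", "wide"):
        raise ValueError(f"unknown layout {layout!r}")
    fh, close = _open_sink(sink)
    try:
        writer = csv.writer(fh, lineterminator="\n")
        if layout == "long":
            writer.writerow(_LONG_HEADER)
            for rec in cohort.records:
                sev = rec.severity.value if rec.severity else "NA"
                resp = rec.actual_response.label if rec.actual_response else "NA"
                for (gene, tp), ct in rec.ct_values.items():
                    writer.writerow([rec.patient_id, sev, resp, gene, tp.value, repr(ct)])
        else:
            genes: dict[str, None] = {}
            for g in cohort.panel.all_genes:
                genes.setdefault(g)
            for rec in cohort.records:
                for g in rec.genes():
                    genes.setdefault(g)
            cols = [f"{g}__{tp.value}" for g in genes for tp in Timepoint]
            writer.writerow(["patient_id", "severity", "actual_response", *cols])
            for rec in cohort.records:
                sev = rec.severity.value if rec.severity else "NA"
                resp = rec.actual_response.label if rec.actual_response else "NA"
                row = [rec.patient_id, sev, resp]
                for g in genes:
                    for tp in Timepoint:
                        row.append(
                            repr(rec.ct_values[(g, tp)]) if rec.has_ct(g, tp) else "NA"
                        )
                writer.writerow(row)
    finally:
        if close:
            fh.close()
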