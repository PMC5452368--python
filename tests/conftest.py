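import numpy as np
import pytest

from mpapredict.ct_data import (
    PatientRecord,
    ResponseLabel,
    Severity,
    Timepoint,
    published_panel,
    Cohort,
)


@pytest.fixture(scope="session")
def panel():
    return published_panel()


def make_record(
    patient_id: str,
    panel,
    ddct: dict[str, float] | float = 0.0,
    hk_ct: float = 20.0,
    dct_pre: float = 4.0,
    severity: Severity | None = None,
    response: ResponseLabel | None = None,
) -> PatientRecord:
    """A fully-populated record with exactly the requested per-gene ΔΔCt."""
    rec = PatientRecord(patient_id=patient_id, severity=severity, actual_response=response)
    rec.set_ct(panel.housekeeping_gene, Timepoint.PRE, hk_ct)
    rec.set_ct(panel.housekeeping_gene, Timepoint.POST, hk_ct)
    for gene in panel.predictor_genes:
        shift = ddct[gene] if isinstance(ddct, dict) else ddct
        rec.set_ct(gene, Timepoint.PRE, hk_ct + dct_pre)
        rec.set_ct(gene, Timepoint.POST, hk_ct + dct_pre + shift)
    return rec


@pytest.fixture
def flat_cohort(panel):
    """Three patients with no expression change anywhere (all folds 1)."""
    records = tuple(make_record(f"P{i}", panel) for i in range(3))
    return Cohort(records=records, panel=panel)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
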