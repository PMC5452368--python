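#!/usr/bin/env python
"""Score the synthetic validation cohort and evaluate the predictions.

Applies the fitted model (from 02_fit_model.py) to the 39-patient
synthetic validation cohort: ΔΔCt fold changes → prediction index →
boundary classification, then tabulates predicted vs actual response
with severity-stratified accuracies and exact 95% binomial CIs.
Writes scores and the evaluation report to results/.
"""

import json
from pathlib import Path

from mpapredict.ct_data import read_ct_table
from mpapredict.evaluation import (
    evaluation_report,
    stratified_accuracy,
    write_report_csv,
    write_report_json,
)
from mpapredict.scoring import PredictionModel, score_cohort, write_scores

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_ct_table(RESULTS / "validation_cohort.csv", layout="long")
    model = PredictionModel.from_json(RESULTS / "fitted_model.json")
    results = score_cohort(cohort, model)
    write_scores(results, RESULTS / "validation_scores.csv")

    by_id = {r.patient_id: r for r in cohort.records}
    triples = [
        (res.predicted, by_id[res.patient_id].actual_response,
         by_id[res.patient_id].severity)
        for res in results
    ]
    report = stratified_accuracy(triples, patient_ids=[r.patient_id for r in results])
    bundle = evaluation_report(report)
    write_report_json(bundle, RESULTS / "validation_report.json")
    write_report_csv(report, RESULTS / "validation_report.csv")

    o = bundle["overall"]
    print(f"scored {len(results)} validation patients against boundary {model.boundary:.4f}")
    print(f"sensitivity {o['sensitivity_pct']}%  (95% CI {o['sensitivity_ci'][0]}–{o['sensitivity_ci'][1]})")
    print(f"specificity {o['specificity_pct']}%  (95% CI {o['specificity_ci'][0]}–{o['specificity_ci'][1]})")
    print(f"accuracy    {o['accuracy_pct']}%")
    for stratum, entry in bundle["strata"].items():
        print(f"  {stratum:12s} n={entry['n']:2d}  accuracy {entry['accuracy_pct']}%")
    print(f"wrote scores and report to {RESULTS}/")


if __name__ == "__main__":
    main()
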