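#!/usr/bin/env python
"""Fit the prediction model on the synthetic training cohort.

Regresses the dummy-coded responses (good = 0, poor = 1) on the 16
fold-change values by ordinary least squares and sets the decision
boundary to the mean of the dummies (5/22 ≈ 0.23 for the default class
balance).  Writes the fitted model JSON to results/.

Run 01_simulate_cohorts.py first.
"""

from pathlib import Path

from mpapredict.ct_data import read_ct_table
from mpapredict.model_fit import TrainingSet, fit_prediction_model

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_ct_table(RESULTS / "training_cohort.csv", layout="long")
    train = TrainingSet.from_cohort(cohort)
    model = fit_prediction_model(train, genes=cohort.panel.predictor_genes)
    model.to_json(RESULTS / "fitted_model.json")
    print(f"fitted on {len(train)} patients")
    print(f"boundary = {model.boundary:.4f} (mean of training dummies)")
    print(f"intercept = {model.intercept:+.3f}")
    for gene, coef in model.coefficients.items():
        print(f"  {gene:12s} {coef:+.3f}")
    print(f"wrote {RESULTS / 'fitted_model.json'}")


if __name__ == "__main__":
    main()
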