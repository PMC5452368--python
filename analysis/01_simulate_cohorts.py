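#!/usr/bin/env python
"""Generate the synthetic training/validation cohort pair.

Emulates the original study design: a 22-patient training cohort
(17 good / 5 poor responders) and a disjoint 39-patient validation
cohort (32 good / 7 poor), with paired pre/post Ct values for the
16-gene panel, 14 decoy genes and the beta-actin housekeeping gene.
Writes both cohorts and their ground truth to results/.
"""

from pathlib import Path

from mpapredict.ct_data import write_ct_table
from mpapredict.simulate import (
    SyntheticConfig,
    generate_training_validation_pair,
    write_ground_truth,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 0


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    config = SyntheticConfig(seed=SEED)
    (train, train_truth), (val, val_truth) = generate_training_validation_pair(config)
    write_ct_table(train, RESULTS / "training_cohort.csv", layout="long")
    write_ground_truth(train_truth, RESULTS / "training_truth.csv")
    write_ct_table(val, RESULTS / "validation_cohort.csv", layout="long")
    write_ground_truth(val_truth, RESULTS / "validation_truth.csv")
    n_poor = sum(1 for r in train if r.actual_response.dummy)
    print(
        f"training cohort: {len(train)} patients ({len(train) - n_poor} good, "
        f"{n_poor} poor); validation cohort: {len(val)} patients"
    )
    print(f"effect |ΔΔCt| = {config.effect_ddct} cycles, Ct noise sd = {config.ct_noise_sd}")
    print(f"wrote 4 CSV files to {RESULTS}/")


if __name__ == "__main__":
    main()
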