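#!/usr/bin/env python
"""Negative controls: zero-effect cohorts and permutation-test calibration.

Two checks that the pipeline does not manufacture signal: (1) on a cohort
with no emotion effect and exchangeable windows, personal-model accuracy
sits at chance — and the same cohort evaluated with 50%-overlap windows
shows the neighborhood-bias inflation directly; (2) the sign-flip
permutation test rejects at its nominal rate under the null.
"""

import argparse
from pathlib import Path

import pandas as pd

from gaitmood.study import null_accuracy_analysis, permutation_type_i_error

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    disjoint = null_accuracy_analysis(seed=args.seed, repeats=2)
    overlap = null_accuracy_analysis(seed=args.seed, repeats=2, overlap=True)
    rate = permutation_type_i_error(seed=args.seed, n_replicates=2000)

    table = pd.DataFrame(
        [
            {"check": "null_accuracy_disjoint_windows",
             "value": disjoint["median_accuracy"], "expected": "~0.50"},
            {"check": "null_accuracy_overlapping_windows",
             "value": overlap["median_accuracy"], "expected": ">0.50 (bias)"},
            {"check": "permutation_type_i_error_at_0.05",
             "value": rate, "expected": "~0.05"},
        ]
    ).round(4)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "null_checks.csv", index=False)
    print(table.to_string(index=False))
    print(
        "with exchangeable windows the null sits at chance; re-introducing "
        "50% window overlap inflates it — neighborhood bias with zero signal"
    )


if __name__ == "__main__":
    main()
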