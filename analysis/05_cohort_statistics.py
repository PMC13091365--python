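#!/usr/bin/env python
"""Longitudinal statistics of the simulated study: baseline normalization,
exact nonparametric volume tests, t-tests for the optical endpoints, and
summary tables.

Reads results/01_simulate/cohort.csv (and 03/04 outputs when present);
writes results/05_stats/.
"""

from pathlib import Path

import pandas as pd

from tumorvasc import cohortstats as cs

IN = Path("results/01_simulate/cohort.csv")
OUT = Path("results/05_stats")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    data = pd.read_csv(IN)

    tests = pd.concat(
        [cs.run_group_tests(data, var) for var in ("volume", "sto2", "thb")],
        ignore_index=True,
    )
    tests.to_csv(OUT / "tests.csv", index=False)

    summaries = pd.concat(
        [cs.summarize(data, var) for var in sorted(data["variable"].unique())],
        ignore_index=True,
    )
    summaries.to_csv(OUT / "summaries.csv", index=False)

    normalized, n_excluded = cs.normalize_to_baseline(
        data, variables=("sto2", "thb", "hbo2", "hhb")
    )
    normalized.to_csv(OUT / "normalized_optical.csv", index=False)

    vol = tests[(tests.variable == "volume") & tests.comparison.str.contains("vs-t")]
    print("between-group volume tests (exact Mann-Whitney):")
    for _, r in vol.iterrows():
        flag = "*" if r.p_value < 0.05 else " "
        print(f"  day {int(r.day):2d}: p = {r.p_value:.4f} {flag}")
    sto2 = tests[(tests.variable == "sto2") & tests.comparison.str.contains("vs-t")]
    print("between-group StO2 tests (Welch t):")
    for _, r in sto2.iterrows():
        flag = "*" if r.p_value < 0.05 else " "
        print(f"  day {int(r.day):2d}: p = {r.p_value:.4f} {flag}")
    print(f"baseline normalization: {n_excluded} animal-series excluded")


if __name__ == "__main__":
    main()
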