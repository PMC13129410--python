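#!/usr/bin/env python
"""Quantify the missing-parentheses error in the biserial conversion.

A worked example first: for dark/light groups 2.40 +- 0.80 vs 2.25 +- 0.75
with 10 per group, the corrected pooled-SD denominator gives d ~ 0.193 while
the erroneous denominator (division applied to one summand only) gives
d ~ 0.065 -- a three-fold attenuation.  The simulation then repeats the
comparison over 10,000 replicated draws at n = 10 and n = 70 per group and
summarizes the replicate-level biserial correlations per variant.

Writes results/effect_size_simulation.csv.
"""

from pathlib import Path

import pandas as pd

from badgemeta.effect_sizes import GroupSummary, rbis_from_group_summary, \
    standardized_difference
from badgemeta.synthetic_data import RbisSimConfig, simulate_rbis_comparison

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20261001


def main() -> None:
    g = GroupSummary(mean_dark=2.40, mean_light=2.25, sd_dark=0.80,
                     sd_light=0.75, n_dark=10, n_light=10)
    print("worked example (dark 2.40+-0.80, light 2.25+-0.75, n=10/10):")
    for variant in ("fixed", "buggy"):
        d = standardized_difference(g, variant)
        r, v = rbis_from_group_summary(g, variant)
        print(f"  {variant:5s}: d = {d:.5f}, r_bis = {r:.5f} (v = {v:.5f})")

    rows = []
    for n in (10, 70):
        res = simulate_rbis_comparison(RbisSimConfig(n_per_group=n, reps=10_000,
                                                     seed=SEED))
        for variant in ("fixed", "buggy"):
            rows.append({
                "n_per_group": n, "variant": variant,
                "mean": round(res[variant]["mean"], 4),
                "sd": round(res[variant]["sd"], 4),
                "min": round(res[variant]["min"], 4),
                "max": round(res[variant]["max"], 4),
            })
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "effect_size_simulation.csv", index=False)
    print("\nsimulation summaries (10,000 replicates each):")
    print(table.to_string(index=False))
    print("\nthe erroneous variant attenuates both the average and the spread "
          "of the biserial correlations at every sample size; written to "
          f"{OUT / 'effect_size_simulation.csv'}")


if __name__ == "__main__":
    main()
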