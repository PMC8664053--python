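#!/usr/bin/env python
"""Reproduce the household sample-size plan for both municipalities.

From the packaged 2010 census stratum populations and municipal household
totals, rebuild the full planning table: person/household ratios, the
households required per stratum for at least 30 expected individuals, the
base sample n0 (the binding stratum's requirement), the inflated field
sample n = floor(n0/0.90), expected individuals per stratum, and the
anticipated precision (95% CI and Cv) over proportions 10-70%.

Writes results/plan_<city>.csv and results/precision_<city>.csv.
"""

from pathlib import Path

from hhsurvey import load_household_totals, load_stratum_populations
from hhsurvey.pipeline import reproduce_planning_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    totals = load_household_totals()
    for city, D in totals.items():
        rep = reproduce_planning_table(load_stratum_populations(city), D, city)
        rep["table"].to_csv(OUT / f"plan_{city}.csv", index=False)
        rep["precision"].to_csv(OUT / f"precision_{city}.csv", index=False)
        print(
            f"{city}: D={D:,} households; base sample n0={rep['n0']} "
            f"(binding stratum = max over 14 sex-age strata); "
            f"field sample n={rep['n']} at 90% anticipated response; "
            f"expected individuals={rep['expected_total']:,} "
            f"(by sex: {rep['expected_by_sex']})"
        )
        for w in rep["warnings"]:
            print(f"  warning: {w}")
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
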