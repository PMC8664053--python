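#!/usr/bin/env python
"""Run one complete synthetic survey end-to-end and report every stage.

A synthetic municipality in the Teresina design regime (census tracts of
~300 households, 14 sex x age strata, correlated binary health indicators)
is generated, PSUs are assembled to a size CV of at most 10%, a = 30 PSUs
and b = 21 households per PSU are drawn by two-stage systematic PPS
(global fraction f = a*b/M), fieldwork is simulated under the three-visit
protocol with refusal and absence, indicator values with item missingness
are completed by predictive mean matching, and design-based estimates with
Cv and deff are produced overall and by sex.

Writes results/synthetic_survey_estimates.csv and
results/synthetic_survey_nrr.json.
"""

import json
from pathlib import Path

import numpy as np

from hhsurvey import (
    FieldParams,
    FrameConfig,
    IndicatorSpec,
    SurveyDataset,
    assign_households,
    build_psus,
    classify_precision,
    draw_sample,
    estimate_proportion,
    generate_frame,
    nrr_report,
    pmm_impute,
    simulate_fieldwork,
    size_cv,
)
from hhsurvey.estimation import estimates_to_frame

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20190901  # fieldwork for the study began September 2018


def main() -> None:
    OUT.mkdir(exist_ok=True)
    master = np.random.SeedSequence(SEED)
    s_frame, s_draw, s_field, s_imp = (
        np.random.default_rng(c) for c in master.spawn(4)
    )

    cfg = FrameConfig(
        n_tracts=70,
        mean_households_per_tract=300,
        mean_persons_per_household=3.33,
        indicator_specs=[
            IndicatorSpec("good_health", prevalence=0.62, icc=0.02,
                          missing_rate=0.05),
            IndicatorSpec("uses_family_health_program", prevalence=0.70,
                          icc=0.03),
        ],
        seed=int(s_frame.integers(2**31)),
    )
    tracts, households, persons = generate_frame(cfg)
    print(f"frame: {len(tracts)} tracts, {len(households):,} households, "
          f"{len(persons):,} persons")

    psus = build_psus(tracts, cv_max=0.10)
    print(f"PSUs: {len(psus)}, size CV = {size_cv(psus):.4f}")
    assigned = assign_households(psus, households)

    a, b = 30, 21
    draw = draw_sample(psus, assigned, a=a, b=b, seed=s_draw)
    print(f"draw: a={a}, b={b}, f = {draw.f:.6f} "
          f"(weight {1 / draw.f:.1f}), {len(draw.households)} households")

    field = FieldParams(p_refusal=0.22, p_absent_visit=0.55)
    outcomes = simulate_fieldwork(draw.households["household_id"], field,
                                  seed=s_field)
    nrr = nrr_report(outcomes).rounded()
    print(f"fieldwork: NRR total {nrr['nrr_total']}% "
          f"(refusal {nrr['nrr_refusal']}%, absence {nrr['nrr_absence']}%); "
          f"{nrr['interviewed']} of {nrr['X']} households interviewed")

    done = outcomes.loc[outcomes["outcome"] == "interviewed", "household_id"]
    resp = persons.merge(
        draw.households.loc[
            draw.households["household_id"].isin(done),
            ["household_id", "psu_id", "weight"],
        ],
        on="household_id",
    )
    miss_before = resp["good_health"].isna().mean()
    resp["sex_num"] = (resp["sex"] == "F").astype(float)
    resp["age_num"] = resp["age_group"].astype("category").cat.codes.astype(float)
    resp = pmm_impute(resp, "good_health", ["sex_num", "age_num"],
                      seed=int(s_imp.integers(2**31)))
    print(f"imputation: {100 * miss_before:.1f}% of good_health imputed by PMM")

    ds = SurveyDataset(resp, f=draw.f, a=a)
    estimates = []
    for ind in ("good_health", "uses_family_health_program"):
        estimates.append(estimate_proportion(ds, ind))
        for sex in ("M", "F"):
            estimates.append(estimate_proportion(ds, ind, domain={"sex": sex}))
    tab = estimates_to_frame(estimates)
    tab.to_csv(OUT / "synthetic_survey_estimates.csv", index=False)
    (OUT / "synthetic_survey_nrr.json").write_text(json.dumps(nrr, indent=2))

    counts = classify_precision(estimates)
    print(tab[["indicator", "domain", "p_hat", "cv", "deff", "n"]]
          .round(3).to_string(index=False))
    print(f"precision: {counts['cv_pass']}/{counts['n_estimates']} estimates "
          f"with Cv < 20%, {counts['deff_le_soft']} with deff <= 1.5, "
          f"{counts['deff_lt_hard']} with deff < 2")
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
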