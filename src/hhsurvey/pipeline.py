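"""End-to-end orchestration: frame -> plan -> PSUs -> draw -> fieldwork ->
estimation -> evaluation, with a replication harness for Monte-Carlo
properties (CI coverage, deff behaviour, realized sample sizes).

Randomness discipline: the master seed spawns one independent stream per
stage (frame, draw, fieldwork, imputation), so changing fieldwork
parameters never perturbs the draw, and replicates use per-replicate
children of each stage stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import (
    Estimate,
    SurveyDataset,
    classify_precision,
    estimate_proportion,
    estimates_to_frame,
)
from .fieldwork import FieldParams, nrr_report, simulate_fieldwork
from .frames import FrameConfig, frame_summary, generate_frame
from .planner import SamplePlan, build_sample_plan
from .psu import assign_households, build_psus
from .sampling import draw_sample

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "run_survey_experiment",
    "reproduce_planning_table",
]


@dataclass
class ExperimentConfig:
    """One replicated synthetic survey experiment."""

    frame: FrameConfig
    a: int                    # PSUs selected at the first stage
    b: int                    # planned households per selected PSU
    field: FieldParams = field(default_factory=FieldParams)
    indicators: Sequence[str] = ()
    replicates: int = 1
    cv_max_psu: float = 0.10
    new_frame_each_replicate: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class ExperimentReport:
    """Per-replicate results plus the frame truth used for coverage."""

    config_manifest: dict
    true_proportions: dict[str, float]
    estimates: pd.DataFrame   # one row per replicate x indicator
    fieldwork: pd.DataFrame   # one row per replicate

    def coverage(self) -> pd.Series:
        """Empirical 95% CI coverage of the frame proportion, per indicator."""
        return self.estimates.groupby("indicator")["covered"].mean()

    def mean_deff(self) -> pd.Series:
        return self.estimates.groupby("indicator")["deff"].mean()

    def precision_summary(self, **kwargs) -> dict[str, int]:
        ests = [
            Estimate(
                indicator=r.indicator, domain="all", p_hat=r.p_hat, se=r.se,
                ci_low=r.ci_low, ci_high=r.ci_high, cv=r.cv, deff=r.deff,
                n=int(r.n), n_psu=int(r.n_psu), n_psu_design=int(r.n_psu),
                var=r.se**2,
            )
            for r in self.estimates.itertuples()
        ]
        return classify_precision(ests, **kwargs)


def _frame_truth(persons: pd.DataFrame, indicators) -> dict[str, float]:
    return {
        ind: float(np.nanmean(persons[ind].to_numpy(dtype=float)))
        for ind in indicators
    }


def run_survey_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run the full pipeline ``config.replicates`` times.

    Each replicate: (re)generate or reuse the synthetic frame, build PSUs,
    draw the two-stage household sample, simulate fieldwork, keep persons
    of interviewed households with the self-weight 1/f, and estimate every
    indicator.  Coverage is evaluated against the frame's person-level
    proportion.
    """
    master = np.random.SeedSequence(config.seed)
    frame_ss, draw_ss, field_ss = master.spawn(3)
    frame_children = frame_ss.spawn(config.replicates)
    draw_children = draw_ss.spawn(config.replicates)
    field_children = field_ss.spawn(config.replicates)

    indicators = list(config.indicators) or [s.name for s in config.frame.indicator_specs]

    tracts = households = persons = None
    psus = None
    hh_assigned = None
    truth: dict[str, float] = {}

    est_rows, field_rows = [], []
    for rep in range(config.replicates):
        if tracts is None or config.new_frame_each_replicate:
            cfg = FrameConfig(
                n_tracts=config.frame.n_tracts,
                mean_households_per_tract=config.frame.mean_households_per_tract,
                mean_persons_per_household=config.frame.mean_persons_per_household,
                stratum_shares=config.frame.stratum_shares,
                indicator_specs=config.frame.indicator_specs,
                min_households_per_tract=config.frame.min_households_per_tract,
                seed=np.random.default_rng(frame_children[rep]).integers(2**31),
            )
            tracts, households, persons = generate_frame(cfg)
            psus = build_psus(tracts, cv_max=config.cv_max_psu)
            hh_assigned = assign_households(psus, households)
            truth = _frame_truth(persons, indicators)

        draw = draw_sample(
            psus, hh_assigned, config.a, config.b,
            seed=np.random.default_rng(draw_children[rep]),
        )
        outcomes = simulate_fieldwork(
            draw.households["household_id"], config.field,
            seed=np.random.default_rng(field_children[rep]),
        )
        rep_nrr = nrr_report(outcomes)
        field_rows.append({"replicate": rep, **rep_nrr.rounded(),
                           "drawn": len(draw.households), "f": draw.f})

        done = outcomes.loc[outcomes["outcome"] == "interviewed", "household_id"]
        sample_hh = draw.households[draw.households["household_id"].isin(done)]
        resp = persons.merge(
            sample_hh[["household_id", "psu_id", "weight"]], on="household_id"
        )
        if resp.empty:
            continue
        ds = SurveyDataset(resp, f=draw.f, a=config.a)
        for ind in indicators:
            try:
                e = estimate_proportion(ds, ind)
            except Exception:
                continue
            est_rows.append(
                {
                    "replicate": rep, "indicator": ind, **e.to_dict(),
                    "covered": bool(e.ci_low <= truth[ind] <= e.ci_high),
                }
            )

    manifest = {
        "seed": config.seed,
        "replicates": config.replicates,
        "a": config.a,
        "b": config.b,
        "n_tracts": config.frame.n_tracts,
        "mean_households_per_tract": config.frame.mean_households_per_tract,
        "field": {
            "p_refusal": config.field.p_refusal,
            "p_absent_visit": config.field.p_absent_visit,
            "max_attempts": config.field.max_attempts,
        },
        "indicators": indicators,
        "cv_max_psu": config.cv_max_psu,
        "new_frame_each_replicate": config.new_frame_each_replicate,
    }
    return ExperimentReport(
        config_manifest=manifest,
        true_proportions=truth,
        estimates=pd.DataFrame(est_rows),
        fieldwork=pd.DataFrame(field_rows),
    )


def reproduce_planning_table(
    populations: pd.DataFrame,
    D: int,
    municipality: str = "",
    m_min: int = 30,
    response_rate: float = 0.90,
    p_grid=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7),
) -> dict:
    """Rebuild the full planning table from a stratum-population table.

    Returns the plan (ratios, household requirements, base/inflated sample
    sizes, expected individuals) and the precision grid over ``p_grid`` —
    the complete planning report for one municipality.
    """
    plan: SamplePlan = build_sample_plan(
        populations, D, municipality=municipality,
        m_min=m_min, response_rate=response_rate,
    )
    return {
        "municipality": municipality,
        "D": int(D),
        "n0": plan.n0,
        "n": plan.n,
        "expected_total": plan.expected_total,
        "expected_by_sex": {k: int(v) for k, v in plan.expected_by_sex().items()},
        "table": plan.table,
        "precision": plan.precision_grid(p_grid),
        "warnings": plan.warnings,
    }
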