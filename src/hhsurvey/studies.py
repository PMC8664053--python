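"""Replicated Monte-Carlo studies of the design's statistical properties.

These studies drive the whole pipeline on synthetic frames and measure the
properties the design promises: confidence-interval coverage under the
self-weighting draw, design-effect behaviour against the Kish
approximation deff ~ 1 + (b_bar - 1) * rho, uniformity of household
inclusion frequencies, and agreement of fieldwork outcome frequencies with
the closed-form contact model.

Frame geometries default to the design's sampling regime — a first-stage
fraction around 0.2 and a small second-stage fraction (around 0.1, as in a
design drawing ~20 households from ~300-household units) — scaled down in
absolute size so each study runs in seconds to minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import SurveyDataset, estimate_proportion
from .fieldwork import FieldParams, outcome_probabilities, simulate_fieldwork
from .frames import FrameConfig, IndicatorSpec, generate_frame
from .psu import assign_households, build_psus
from .sampling import draw_sample

__all__ = [
    "coverage_study",
    "kish_deff_study",
    "inclusion_frequency_study",
    "fieldwork_frequency_study",
]


def _survey_world(n_tracts, hh_per_tract, persons_per_hh, prevalence, icc, seed):
    cfg = FrameConfig(
        n_tracts=n_tracts,
        mean_households_per_tract=hh_per_tract,
        fixed_tract_sizes=True,
        mean_persons_per_household=persons_per_hh,
        indicator_specs=[IndicatorSpec("y", prevalence, icc)],
        seed=seed,
    )
    tracts, households, persons = generate_frame(cfg)
    psus = build_psus(tracts)
    assigned = assign_households(psus, households)
    return psus, assigned, persons


@dataclass
class CoverageResult:
    coverage: float
    mean_p_hat: float
    truth: float
    replicates: int
    n_mean: float


def coverage_study(
    seed: int,
    replicates: int = 500,
    n_tracts: int = 150,
    hh_per_tract: int = 100,
    a: int = 30,
    b: int = 10,
    prevalence: float = 0.3,
) -> CoverageResult:
    """Empirical 95% CI coverage over replicate draws from an icc=0 frame.

    One fixed frame; the randomness studied is the two-stage draw, so the
    coverage measured is the design-based coverage of the frame's
    person-level proportion.
    """
    psus, assigned, persons = _survey_world(
        n_tracts, hh_per_tract, 2.5, prevalence, 0.0, seed
    )
    truth = float(persons["y"].mean())
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    cover = 0
    p_hats, ns = [], []
    for _ in range(replicates):
        d = draw_sample(psus, assigned, a=a, b=b, seed=rng)
        resp = persons.merge(
            d.households[["household_id", "psu_id", "weight"]], on="household_id"
        )
        e = estimate_proportion(SurveyDataset(resp), "y")
        cover += e.ci_low <= truth <= e.ci_high
        p_hats.append(e.p_hat)
        ns.append(e.n)
    return CoverageResult(
        coverage=cover / replicates,
        mean_p_hat=float(np.mean(p_hats)),
        truth=truth,
        replicates=replicates,
        n_mean=float(np.mean(ns)),
    )


def kish_deff_study(
    seed: int,
    rhos=(0.0, 0.02, 0.05),
    n_frames: int = 30,
    draws_per_frame: int = 12,
    n_tracts: int = 100,
    hh_per_tract: int = 20,
    a: int = 25,
    b: int = 20,
    prevalence: float = 0.3,
) -> pd.DataFrame:
    """Mean estimated deff versus the Kish approximation per target rho.

    Equal cluster takes: one person per household and b equal to the PSU
    size, so b_bar = b exactly and Kish predicts 1 + (b - 1) * rho.  Frames
    are regenerated so the tract random effects are themselves replicated.
    """
    rows = []
    master = np.random.SeedSequence(seed)
    for rho in rhos:
        deffs = []
        for child in master.spawn(n_frames):
            fseed = int(np.random.default_rng(child).integers(2**31))
            psus, assigned, persons = _survey_world(
                n_tracts, hh_per_tract, 1.0, prevalence, rho, fseed
            )
            rng = np.random.default_rng(fseed ^ 0x5DEECE)
            for _ in range(draws_per_frame):
                d = draw_sample(psus, assigned, a=a, b=b, seed=rng)
                resp = persons.merge(
                    d.households[["household_id", "psu_id", "weight"]],
                    on="household_id",
                )
                e = estimate_proportion(SurveyDataset(resp), "y")
                if not np.isnan(e.deff):
                    deffs.append(e.deff)
        rows.append(
            {
                "rho": rho,
                "kish": 1 + (b - 1) * rho,
                "mean_deff": float(np.mean(deffs)),
                "n_reps": len(deffs),
                "b_bar": b,
            }
        )
    return pd.DataFrame(rows)


def inclusion_frequency_study(
    seed: int,
    replicates: int = 20_000,
    n_tracts: int = 10,
    hh_per_tract: int = 200,
    a: int = 5,
    b: int = 10,
) -> pd.DataFrame:
    """Per-household selection frequency over replicate two-stage draws.

    On an equal-size frame the self-weighting property says every
    household's inclusion probability is exactly f = a*b/M; the returned
    table carries each household's empirical frequency and the binomial
    standard error of the Monte-Carlo estimate.
    """
    psus, assigned, _ = _survey_world(n_tracts, hh_per_tract, 1.0, 0.5, 0.0, seed)
    total_m = int(sum(p.M for p in psus))
    f = a * b / total_m
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    ids = assigned["household_id"].to_numpy()
    pos = {h: i for i, h in enumerate(ids)}
    counts = np.zeros(len(ids))
    for _ in range(replicates):
        d = draw_sample(psus, assigned, a=a, b=b, seed=rng)
        for h in d.households["household_id"]:
            counts[pos[h]] += 1
    freq = counts / replicates
    se = np.sqrt(f * (1 - f) / replicates)
    return pd.DataFrame(
        {
            "household_id": ids,
            "freq": freq,
            "f": f,
            "se": se,
            "z": (freq - f) / se,
        }
    )


def fieldwork_frequency_study(
    seed: int,
    n_households: int = 10_000,
    params: FieldParams | None = None,
) -> pd.DataFrame:
    """Simulated outcome frequencies against the closed-form contact model."""
    params = params or FieldParams(p_refusal=0.2, p_absent_visit=0.5)
    out = simulate_fieldwork(
        [f"H{i:06d}" for i in range(n_households)], params, seed=seed
    )
    freq = out["outcome"].value_counts(normalize=True)
    probs = outcome_probabilities(params)
    rows = []
    for k, p in probs.items():
        se = float(np.sqrt(p * (1 - p) / n_households)) if 0 < p < 1 else 0.0
        rows.append(
            {
                "outcome": k,
                "expected": p,
                "observed": float(freq.get(k, 0.0)),
                "se": se,
            }
        )
    return pd.DataFrame(rows)
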