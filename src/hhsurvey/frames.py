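"""Synthetic census frames: tracts, households, persons, health indicators.

The downstream design (PSU construction, two-stage systematic PPS drawing,
design-based estimation) assumes a frame of census tracts of roughly 300
households / 1,000 inhabitants, a population stratified into 14 sex ×
age-group cells, and binary health indicators whose within-tract
(intra-cluster) correlation drives the design effect.  This module
generates frames with exactly that structure, so every downstream stage
can be exercised and validated without any external data.

Indicators are generated from a logit-normal tract-level random effect:
each tract t receives z_t ~ N(0, 1), and a person in domain d of tract t
carries the indicator with probability expit(mu_d + sigma_d * z_t).
(mu_d, sigma_d) are calibrated numerically so that the marginal prevalence
equals the requested value and the intra-cluster correlation

    rho = Var(p_t) / (p * (1 - p))

equals the requested ``icc``.  Missingness is applied completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from ._util import AGE_GROUPS, SEXES, round_half_up, rng_from

__all__ = [
    "IndicatorSpec",
    "FrameConfig",
    "generate_frame",
    "frame_summary",
    "default_stratum_shares",
    "calibrate_logit_normal",
]


class FrameConfigError(ValueError):
    """Raised for an invalid frame configuration."""


def default_stratum_shares(municipality: str = "Teresina") -> dict[tuple[str, str], float]:
    """Stratum shares taken from the packaged census table.

    The share of each sex × age-group cell in the municipality's census
    population; a realistic default age/sex structure for synthetic frames.
    """
    from .tables import load_stratum_populations

    df = load_stratum_populations(municipality)
    total = df["N"].sum()
    return {(r.sex, r.age_group): r.N / total for r in df.itertuples()}


@dataclass(frozen=True)
class IndicatorSpec:
    """A binary health indicator to attach to generated persons.

    prevalence may be a single probability (same in every domain) or a
    mapping ``(sex, age_group) -> probability``.  ``icc`` is the target
    within-tract intra-cluster correlation rho; ``missing_rate`` is the
    MCAR probability that a person's value is unobserved.
    """

    name: str
    prevalence: float | Mapping[tuple[str, str], float] = 0.5
    icc: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self):
        prevs = (
            [self.prevalence]
            if np.isscalar(self.prevalence)
            else list(self.prevalence.values())
        )
        for p in prevs:
            if not 0.0 <= p <= 1.0:
                raise FrameConfigError(f"prevalence {p} outside [0, 1]")
        if not 0.0 <= self.icc < 1.0:
            raise FrameConfigError(f"icc {self.icc} outside [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise FrameConfigError(f"missing_rate {self.missing_rate} outside [0, 1)")

    def prevalence_for(self, sex: str, age_group: str) -> float:
        if np.isscalar(self.prevalence):
            return float(self.prevalence)
        return float(self.prevalence[(sex, age_group)])


@dataclass
class FrameConfig:
    """Parameters of a synthetic municipality.

    Defaults emulate the census-tract scale the design assumes: a mean of
    300 households per tract and a household size giving roughly 1,000
    inhabitants per tract.  Tract sizes are Poisson around the mean,
    truncated below at ``min_households_per_tract`` to create realistic
    size variation without degenerate tracts.
    """

    n_tracts: int
    mean_households_per_tract: float = 300.0
    mean_persons_per_household: float = 3.33
    stratum_shares: Mapping[tuple[str, str], float] | None = None
    indicator_specs: Sequence[IndicatorSpec] = field(default_factory=tuple)
    min_households_per_tract: int = 50
    fixed_tract_sizes: bool = False  # every tract exactly round(mean) households
    seed: int = 0

    def __post_init__(self):
        if self.n_tracts < 1:
            raise FrameConfigError("n_tracts must be >= 1")
        if self.mean_households_per_tract < 1:
            raise FrameConfigError("mean_households_per_tract must be >= 1")
        if self.mean_persons_per_household <= 0:
            raise FrameConfigError("mean_persons_per_household must be > 0")
        if self.stratum_shares is None:
            self.stratum_shares = default_stratum_shares()
        total = sum(self.stratum_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise FrameConfigError(f"stratum_shares sum to {total}, expected 1")
        for sex, age in self.stratum_shares:
            if sex not in SEXES or age not in AGE_GROUPS:
                raise FrameConfigError(f"unknown stratum {(sex, age)}")


# ---------------------------------------------------------------------------
# logit-normal calibration

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(61)


def _logit_normal_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Mean and variance of expit(mu + sigma*Z), Z ~ N(0,1), by quadrature."""
    vals = expit(mu + sigma * np.sqrt(2.0) * _GH_NODES)
    w = _GH_WEIGHTS / np.sqrt(np.pi)
    m = float(np.sum(w * vals))
    v = float(np.sum(w * vals**2)) - m * m
    return m, max(v, 0.0)


def calibrate_logit_normal(p: float, icc: float) -> tuple[float, float]:
    """Find (mu, sigma) so the logit-normal mixture has mean p and ICC icc.

    With sigma fixed, mu is solved so the marginal prevalence is p; sigma
    is then solved so Var(p_t) = icc * p * (1 - p).  icc = 0 gives the
    degenerate sigma = 0, mu = logit(p).
    """
    if not 0.0 < p < 1.0:
        if icc > 0:
            raise FrameConfigError("icc > 0 requires 0 < prevalence < 1")
        return (np.inf if p == 1.0 else -np.inf), 0.0
    if icc == 0.0:
        return float(logit(p)), 0.0

    def mu_for(sigma: float) -> float:
        return brentq(lambda m: _logit_normal_moments(m, sigma)[0] - p, -40.0, 40.0)

    target = icc * p * (1.0 - p)

    def gap(sigma: float) -> float:
        return _logit_normal_moments(mu_for(sigma), sigma)[1] - target

    hi = 1.0
    while gap(hi) < 0.0:
        hi *= 2.0
        if hi > 64.0:
            raise FrameConfigError(f"cannot attain icc={icc} at prevalence={p}")
    sigma = brentq(gap, 1e-9, hi, xtol=1e-10)
    return float(mu_for(sigma)), float(sigma)


# ---------------------------------------------------------------------------
# generation

def _zero_truncated_poisson(mean: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Household sizes: zero-truncated Poisson with the requested mean."""
    if mean <= 1.0:
        return np.ones(size, dtype=int)
    # solve lam / (1 - exp(-lam)) = mean
    lam = brentq(lambda L: L / (1.0 - np.exp(-L)) - mean, 1e-9, mean)
    out = rng.poisson(lam, size)
    while True:
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.poisson(lam, int(zero.sum()))


def generate_frame(
    config: FrameConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic municipality.

    Returns ``(tracts, households, persons)`` DataFrames.  ``tracts`` has
    tract_id, n_households and one population column per sex × age-group
    stratum; ``households`` has household_id, tract_id, n_persons;
    ``persons`` has person_id, household_id, tract_id, sex, age_group and
    one column per indicator (float, NaN = missing).

    Reproducible: the same config (including seed) yields identical frames.
    """
    rng = rng_from(config.seed)
    width = max(4, len(str(config.n_tracts)))

    if config.fixed_tract_sizes:
        sizes = np.full(config.n_tracts, round_half_up(config.mean_households_per_tract))
    else:
        sizes = rng.poisson(config.mean_households_per_tract, config.n_tracts)
        sizes = np.maximum(sizes, config.min_households_per_tract).astype(int)
    tract_ids = np.array([f"T{i:0{width}d}" for i in range(1, config.n_tracts + 1)])

    households = pd.DataFrame(
        {
            "tract_id": np.repeat(tract_ids, sizes),
        }
    )
    n_hh = len(households)
    households["household_id"] = [f"H{i:07d}" for i in range(1, n_hh + 1)]
    households["n_persons"] = _zero_truncated_poisson(
        config.mean_persons_per_household, n_hh, rng
    )
    households = households[["household_id", "tract_id", "n_persons"]]

    strata = list(config.stratum_shares.keys())
    shares = np.array([config.stratum_shares[s] for s in strata], dtype=float)
    shares = shares / shares.sum()

    n_persons = int(households["n_persons"].sum())
    stratum_idx = rng.choice(len(strata), size=n_persons, p=shares)
    persons = pd.DataFrame(
        {
            "person_id": [f"P{i:08d}" for i in range(1, n_persons + 1)],
            "household_id": np.repeat(households["household_id"].to_numpy(),
                                      households["n_persons"].to_numpy()),
            "tract_id": np.repeat(households["tract_id"].to_numpy(),
                                  households["n_persons"].to_numpy()),
            "sex": [strata[i][0] for i in stratum_idx],
            "age_group": [strata[i][1] for i in stratum_idx],
        }
    )

    tract_pos = {t: i for i, t in enumerate(tract_ids)}
    person_tract = persons["tract_id"].map(tract_pos).to_numpy()

    for spec in config.indicator_specs:
        z = rng.standard_normal(config.n_tracts)
        prob = np.empty(n_persons)
        for sex, age in {(s, a) for s, a in zip(persons["sex"], persons["age_group"])}:
            mu, sigma = calibrate_logit_normal(spec.prevalence_for(sex, age), spec.icc)
            mask = (persons["sex"].to_numpy() == sex) & (
                persons["age_group"].to_numpy() == age
            )
            prob[mask] = expit(mu + sigma * z[person_tract[mask]])
        values = (rng.random(n_persons) < prob).astype(float)
        if spec.missing_rate > 0:
            values[rng.random(n_persons) < spec.missing_rate] = np.nan
        persons[spec.name] = values

    counts = (
        persons.groupby(["tract_id", "sex", "age_group"], observed=True)
        .size()
        .unstack(["sex", "age_group"], fill_value=0)
    )
    tracts = pd.DataFrame({"tract_id": tract_ids, "n_households": sizes})
    for sex in SEXES:
        for age in AGE_GROUPS:
            col = f"{sex}_{age}"
            if (sex, age) in counts.columns:
                tracts[col] = (
                    counts[(sex, age)].reindex(tract_ids, fill_value=0).to_numpy()
                )
            else:
                tracts[col] = 0
    return tracts, households, persons


def frame_summary(tracts: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse a tract table to stratum population counts + household total.

    Returns a (sex, age_group, N) DataFrame in the shape the planner
    consumes, and the total number of households in the frame.
    """
    if tracts.empty:
        raise ValueError("empty frame")
    rows = []
    for sex in SEXES:
        for age in AGE_GROUPS:
            col = f"{sex}_{age}"
            n = int(tracts[col].sum()) if col in tracts.columns else 0
            rows.append({"sex": sex, "age_group": age, "N": n})
    return pd.DataFrame(rows), int(tracts["n_households"].sum())
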