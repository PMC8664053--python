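"""Household contact simulation and non-response accounting.

Field protocol: a team visits each sampled household up to ``max_attempts``
times (default 3, on different days).  At the first visit that finds
someone home, the household either consents (interviewed) or declines
(non-response by refusal).  A household never found at home across all
attempts is non-response by absence.

Rates over X sampled households, with x_r refusals and x_a absences:

    NRR-Total   = 100 * (x_r + x_a) / X
    NRR-Refusal = 100 * x_r / X
    NRR-Absence = 100 * x_a / X

so NRR-Refusal + NRR-Absence = NRR-Total exactly before rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import rng_from

__all__ = [
    "FieldParams",
    "NRRReport",
    "simulate_fieldwork",
    "nrr_report",
    "outcome_probabilities",
]

OUTCOMES = ("interviewed", "refusal", "absence")


@dataclass(frozen=True)
class FieldParams:
    """Contact-process parameters.

    p_absent_visit: probability a single visit finds nobody home
    (independent across visits); p_refusal: probability the household
    declines once contacted; max_attempts: visits before the household is
    written off as absent.
    """

    p_refusal: float = 0.0
    p_absent_visit: float = 0.0
    max_attempts: int = 3
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_refusal <= 1.0:
            raise ValueError("p_refusal outside [0, 1]")
        if not 0.0 <= self.p_absent_visit <= 1.0:
            raise ValueError("p_absent_visit outside [0, 1]")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")


def outcome_probabilities(params: FieldParams) -> dict[str, float]:
    """Closed-form outcome distribution of the contact process.

    P(absence) = q^T with q = p_absent_visit, T = max_attempts;
    P(refusal) = (1 - q^T) * p_refusal;
    P(interviewed) = (1 - q^T) * (1 - p_refusal).
    """
    reach = 1.0 - params.p_absent_visit ** params.max_attempts
    return {
        "interviewed": reach * (1.0 - params.p_refusal),
        "refusal": reach * params.p_refusal,
        "absence": 1.0 - reach,
    }


def simulate_fieldwork(household_ids, params: FieldParams, seed=None) -> pd.DataFrame:
    """Simulate the contact process for every sampled household.

    Returns a DataFrame (household_id, outcome, attempts) where attempts is
    the number of visits actually made: first contact resolves the
    household, absence consumes all max_attempts visits.
    """
    ids = list(household_ids)
    rng = rng_from(params.seed if seed is None else seed)
    n = len(ids)
    T = params.max_attempts

    visits_home = rng.random((n, T)) >= params.p_absent_visit  # True = someone home
    any_home = visits_home.any(axis=1)
    first_home = np.where(any_home, visits_home.argmax(axis=1) + 1, T)
    refuses = rng.random(n) < params.p_refusal

    outcome = np.where(
        ~any_home, "absence", np.where(refuses, "refusal", "interviewed")
    )
    return pd.DataFrame(
        {"household_id": ids, "outcome": outcome, "attempts": first_home}
    )


@dataclass(frozen=True)
class NRRReport:
    """Non-response bookkeeping over the X households in the sample."""

    X: int
    interviewed: int
    x_refusal: int
    x_absence: int

    @property
    def x(self) -> int:
        return self.x_refusal + self.x_absence

    @property
    def nrr_total(self) -> float:
        return 100.0 * self.x / self.X

    @property
    def nrr_refusal(self) -> float:
        return 100.0 * self.x_refusal / self.X

    @property
    def nrr_absence(self) -> float:
        return 100.0 * self.x_absence / self.X

    def rounded(self) -> dict[str, float]:
        """Report form: rates to 1 decimal."""
        return {
            "X": self.X,
            "interviewed": self.interviewed,
            "x_refusal": self.x_refusal,
            "x_absence": self.x_absence,
            "nrr_total": round(self.nrr_total, 1),
            "nrr_refusal": round(self.nrr_refusal, 1),
            "nrr_absence": round(self.nrr_absence, 1),
        }


def nrr_report(outcomes: pd.DataFrame) -> NRRReport:
    """Compute the non-response report from per-household outcomes."""
    X = len(outcomes)
    if X == 0:
        raise ValueError("no households in the sample")
    counts = outcomes["outcome"].value_counts()
    bad = set(counts.index) - set(OUTCOMES)
    if bad:
        raise ValueError(f"unknown outcomes: {sorted(bad)}")
    return NRRReport(
        X=X,
        interviewed=int(counts.get("interviewed", 0)),
        x_refusal=int(counts.get("refusal", 0)),
        x_absence=int(counts.get("absence", 0)),
    )
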