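"""Sample-size planning for a stratified two-stage household survey.

The planning logic works backwards from a precision goal: every sex ×
age-group stratum should contribute at least ``m_min`` (default 30)
individuals, the threshold at which the sampling distribution of a
proportion is comfortably normal.  Given census counts N_s per stratum and
the municipal household total D:

* r_s = N_s / D            persons of stratum s expected per household,
* h_s = round(m_min / r_s) households needed to expect m_min persons of s,
* n0  = max_s h_s          the base household sample (the binding stratum),
* n   = floor(n0 / response_rate)   the field sample after inflating for
                                    an anticipated response rate,
* e_s = round(r_s * n0)    expected individuals per stratum.

A precision profile then reports, for a stratum's expected count n and a
hypothesised proportion p, the standard error sqrt(p(1-p)/n), the 95% CI
and the coefficient of variation Cv-p = 100 * se / p — the planning
criterion being Cv below 20%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import round_half_up, rng_from

__all__ = [
    "person_household_ratio",
    "households_for_minimum",
    "base_sample_size",
    "inflate_for_nonresponse",
    "expected_individuals",
    "precision_profile",
    "build_sample_plan",
    "SamplePlan",
    "PrecisionProfile",
]


def person_household_ratio(N: float, D: float) -> float:
    """Expected persons of a stratum per household: N / D, unrounded.

    Display rounding (4 decimals in reports) happens only at report time.
    """
    if D <= 0:
        raise ValueError("municipal household total D must be positive")
    if N < 0:
        raise ValueError("stratum population N must be non-negative")
    return N / D


def households_for_minimum(N: float, D: float, m_min: int = 30) -> int:
    """Households needed so the stratum expects at least ``m_min`` persons.

    Round-to-nearest of m_min * D / N using the unrounded person/household
    ratio.  A stratum with N = 0 can never attain the minimum.
    """
    if N <= 0:
        raise ValueError("stratum with N = 0 cannot attain the per-stratum minimum")
    return round_half_up(m_min * D / N)


def base_sample_size(populations, D: float, m_min: int = 30) -> int:
    """Base household sample n0: the max requirement over all strata.

    ``populations`` is an iterable of stratum census counts N (or a
    DataFrame with an ``N`` column).
    """
    if isinstance(populations, pd.DataFrame):
        populations = populations["N"].to_numpy()
    populations = list(populations)
    if not populations:
        raise ValueError("at least one stratum is required")
    return max(households_for_minimum(N, D, m_min) for N in populations)


def inflate_for_nonresponse(n0: int, response_rate: float = 0.90) -> int:
    """Inflate the base sample for anticipated non-response: floor(n0 / rate)."""
    if not 0.0 < response_rate <= 1.0:
        raise ValueError("response_rate must be in (0, 1]")
    return math.floor(n0 / response_rate)


def expected_individuals(ratios, n0: int):
    """Expected individuals per stratum at household sample n0.

    Per-stratum count = round-to-nearest of r * n0 with the unrounded
    ratio; totals are sums of the rounded counts.  Accepts a mapping
    ``stratum -> ratio`` (returns a dict plus totals) or a plain iterable
    (returns a list plus grand total).
    """
    if n0 < 0:
        raise ValueError("n0 must be non-negative")
    if isinstance(ratios, dict):
        counts = {k: round_half_up(r * n0) for k, r in ratios.items()}
        return counts, sum(counts.values())
    counts = [round_half_up(r * n0) for r in ratios]
    return counts, sum(counts)


@dataclass(frozen=True)
class PrecisionProfile:
    """Anticipated precision of a proportion estimate at sample size n."""

    p: float
    n: int
    z: float
    se: float
    ci_low: float   # percent
    ci_high: float  # percent
    cv: float       # percent, Cv-p = 100 * se / p

    def round1(self) -> "PrecisionProfile":
        """Copy with CI bounds and Cv rounded to 1 decimal (report form)."""
        return PrecisionProfile(
            self.p, self.n, self.z, self.se,
            round(self.ci_low, 1), round(self.ci_high, 1), round(self.cv, 1),
        )


def precision_profile(
    n: int,
    p: float,
    z: float = 1.96,
    *,
    method: str = "analytic",
    replicates: int = 10_000,
    seed=None,
    fpc_N: int | None = None,
) -> PrecisionProfile:
    """Anticipated CI and Cv-p for a proportion p estimated from n persons.

    ``method="analytic"`` uses the closed form se = sqrt(p(1-p)/n);
    ``method="mc"`` estimates se by binomial resampling (the two agree
    within Monte-Carlo error).  ``fpc_N`` optionally applies a finite
    population correction sqrt(1 - n/N); off by default.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < p < 1.0:
        raise ValueError("p must be strictly inside (0, 1)")
    if method == "analytic":
        se = math.sqrt(p * (1.0 - p) / n)
    elif method == "mc":
        rng = rng_from(seed)
        draws = rng.binomial(n, p, size=replicates) / n
        se = float(np.std(draws, ddof=1))
    else:
        raise ValueError(f"unknown method {method!r}")
    if fpc_N is not None:
        if fpc_N <= n:
            raise ValueError("fpc population must exceed n")
        se *= math.sqrt(1.0 - n / fpc_N)
    return PrecisionProfile(
        p=p, n=n, z=z, se=se,
        ci_low=100.0 * (p - z * se),
        ci_high=100.0 * (p + z * se),
        cv=100.0 * se / p,
    )


@dataclass
class SamplePlan:
    """Full planning table for one municipality.

    Mirrors the planning-table blocks: census populations, person/household
    ratios, per-stratum household requirements, the base and inflated
    household sample sizes, and expected individuals.
    """

    municipality: str
    D: int
    m_min: int
    response_rate: float
    table: pd.DataFrame          # per-stratum: sex, age_group, N, ratio, households, expected
    n0: int
    n: int
    expected_total: int
    warnings: list[str] = field(default_factory=list)

    def expected_by_sex(self) -> pd.Series:
        return self.table.groupby("sex", observed=True)["expected"].sum()

    def precision_grid(
        self, p_values=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7), z: float = 1.96
    ) -> pd.DataFrame:
        """Precision profiles for every stratum's expected n over a p grid."""
        rows = []
        for r in self.table.itertuples():
            if r.expected < 1:
                continue
            for p in p_values:
                prof = precision_profile(int(r.expected), p, z).round1()
                rows.append(
                    {
                        "sex": r.sex, "age_group": r.age_group, "n": int(r.expected),
                        "p": p, "ci_low": prof.ci_low, "ci_high": prof.ci_high,
                        "cv": prof.cv,
                    }
                )
        return pd.DataFrame(rows)


def build_sample_plan(
    populations: pd.DataFrame,
    D: int,
    municipality: str = "",
    m_min: int = 30,
    response_rate: float = 0.90,
) -> SamplePlan:
    """Assemble the full plan from a (sex, age_group, N) table and total D."""
    if populations.empty:
        raise ValueError("empty population table")
    tab = populations.loc[:, ["sex", "age_group", "N"]].copy()
    tab["ratio"] = [person_household_ratio(N, D) for N in tab["N"]]
    tab["households"] = [households_for_minimum(N, D, m_min) for N in tab["N"]]
    n0 = int(tab["households"].max())
    n = inflate_for_nonresponse(n0, response_rate)
    counts, total = expected_individuals(list(tab["ratio"]), n0)
    tab["expected"] = counts

    warnings = []
    for r in tab.itertuples():
        if r.ratio * n0 < m_min and r.households == n0:
            warnings.append(
                f"binding stratum ({r.sex}, {r.age_group}): expected count "
                f"{r.ratio * n0:.3f} is marginally below the target {m_min} "
                "because the household requirement was rounded to nearest"
            )
    return SamplePlan(
        municipality=municipality, D=int(D), m_min=m_min,
        response_rate=response_rate, table=tab, n0=n0, n=n,
        expected_total=int(total), warnings=warnings,
    )
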