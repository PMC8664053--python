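"""Design-based estimation of proportions with linearized variance.

Point estimate: the weighted ratio estimator

    p_hat = sum(w_k y_k) / sum(w_k)        over respondents in the domain.

Variance: ultimate-cluster Taylor linearization — first-stage units (PSUs)
are treated as independent with-replacement draws, absorbing all later
stages.  With m PSUs in the design, W = sum of domain weights and per-PSU
linearized totals

    z_i = sum_{k in PSU i, domain} w_k (y_k - p_hat) / W,

    v(p_hat) = m / (m - 1) * sum_i (z_i - z_bar)^2.

PSUs with no domain members stay in the sum with z_i = 0 (the standard
design-based subpopulation convention).  Confidence intervals use a
t critical value with m - 1 degrees of freedom (z optionally), truncated
to [0, 1].

Precision diagnostics:

    Cv-p  = 100 * se / p_hat                (criterion: below 20%)
    deff  = v(p_hat) / (p_hat (1 - p_hat) / n)   (SRS-with-replacement
            denominator; criteria: at most 1.5, and below 2)

No finite-population correction is applied: the with-replacement
approximation is the standard treatment for self-weighting systematic-PPS
designs and what mainstream survey software reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurveyDataset",
    "Estimate",
    "estimate_proportion",
    "design_effect",
    "cv_of",
    "classify_precision",
]


class EstimationError(ValueError):
    """Raised when an estimate is not defined for the given data."""


@dataclass
class SurveyDataset:
    """Person-level survey records plus design metadata.

    ``data`` must carry a PSU identifier column, a weight column, and one
    column per indicator (float; NaN = missing).  ``f`` and ``a`` record
    the global sampling fraction and the number of first-stage selections.
    """

    data: pd.DataFrame
    f: float | None = None
    a: int | None = None
    psu_col: str = "psu_id"
    weight_col: str = "weight"

    def __post_init__(self):
        for col in (self.psu_col, self.weight_col):
            if col not in self.data.columns:
                raise EstimationError(f"dataset lacks required column {col!r}")
        if (self.data[self.weight_col] <= 0).any():
            raise EstimationError("weights must be strictly positive")


@dataclass(frozen=True)
class Estimate:
    """A design-based proportion estimate and its precision diagnostics."""

    indicator: str
    domain: str
    p_hat: float
    se: float
    ci_low: float
    ci_high: float
    cv: float          # percent; NaN when p_hat == 0
    deff: float        # NaN when p_hat in {0, 1}
    n: int             # respondents in the domain
    n_psu: int         # PSUs contributing domain respondents
    n_psu_design: int  # PSUs in the design (variance degrees of freedom + 1)
    var: float

    def to_dict(self) -> dict:
        return {
            "indicator": self.indicator, "domain": self.domain,
            "p_hat": self.p_hat, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "cv": self.cv, "deff": self.deff,
            "n": self.n, "n_psu": self.n_psu,
        }


def _domain_mask(data: pd.DataFrame, domain) -> tuple[np.ndarray, str]:
    if domain is None:
        return np.ones(len(data), dtype=bool), "all"
    if isinstance(domain, dict):
        mask = np.ones(len(data), dtype=bool)
        for col, val in domain.items():
            mask &= (data[col] == val).to_numpy()
        label = ",".join(f"{c}={v}" for c, v in domain.items())
        return mask, label
    return np.asarray(domain, dtype=bool), "custom"


def estimate_proportion(
    dataset: SurveyDataset | pd.DataFrame,
    indicator: str,
    domain=None,
    *,
    ci: str = "t",
    alpha: float = 0.05,
) -> Estimate:
    """Estimate a proportion for a domain with linearized variance.

    ``domain`` may be None (whole sample), a dict of column -> value, or a
    boolean mask.  Rows with a missing indicator value are non-respondents
    for this indicator and drop from the numerator/denominator, but their
    PSUs remain in the variance computation.
    """
    ds = dataset if isinstance(dataset, SurveyDataset) else SurveyDataset(dataset)
    data, psu_col, w_col = ds.data, ds.psu_col, ds.weight_col
    if indicator not in data.columns:
        raise EstimationError(f"unknown indicator {indicator!r}")

    dmask, dlabel = _domain_mask(data, domain)
    y_all = data[indicator].to_numpy(dtype=float)
    resp = dmask & ~np.isnan(y_all)
    n = int(resp.sum())
    if n == 0:
        raise EstimationError(f"empty domain {dlabel!r} for {indicator!r}")

    w = data[w_col].to_numpy(dtype=float)
    psu_all = data[psu_col].to_numpy()
    design_psus = pd.unique(psu_all)
    m = len(design_psus)
    contributing = pd.unique(psu_all[resp])
    n_psu = len(contributing)
    if n_psu < 2:
        raise EstimationError(
            f"variance undefined: only {n_psu} PSU contributes to domain {dlabel!r}"
        )

    W = float(w[resp].sum())
    p_hat = float((w[resp] * y_all[resp]).sum() / W)

    # per-PSU linearized totals over ALL design PSUs (zeros retained)
    u = np.zeros(len(data))
    u[resp] = w[resp] * (y_all[resp] - p_hat) / W
    z = pd.Series(u).groupby(pd.Series(psu_all)).sum().reindex(design_psus, fill_value=0.0)
    zbar = float(z.mean())
    var = m / (m - 1) * float(((z - zbar) ** 2).sum())
    se = math.sqrt(var)

    if ci == "t":
        crit = float(stats.t.ppf(1 - alpha / 2, df=m - 1))
    elif ci == "z":
        crit = float(stats.norm.ppf(1 - alpha / 2))
    else:
        raise ValueError(f"unknown ci method {ci!r}")
    lo = max(0.0, p_hat - crit * se)
    hi = min(1.0, p_hat + crit * se)

    cv = float("nan") if p_hat == 0 else 100.0 * se / p_hat
    if 0.0 < p_hat < 1.0:
        deff = var / (p_hat * (1.0 - p_hat) / n)
    else:
        deff = float("nan")

    return Estimate(
        indicator=indicator, domain=dlabel, p_hat=p_hat, se=se,
        ci_low=lo, ci_high=hi, cv=cv, deff=deff,
        n=n, n_psu=n_psu, n_psu_design=m, var=var,
    )


def design_effect(estimate: Estimate) -> float:
    """deff = design variance over the SRS-with-replacement variance.

    Undefined (NaN) when the estimated proportion is 0 or 1.
    """
    if not 0.0 < estimate.p_hat < 1.0:
        return float("nan")
    return estimate.var / (estimate.p_hat * (1.0 - estimate.p_hat) / estimate.n)


def cv_of(estimate: Estimate, decimals: int | None = None) -> float:
    """Cv-p = 100 * se / p_hat; undefined (NaN) at p_hat = 0."""
    if estimate.p_hat == 0:
        return float("nan")
    cv = 100.0 * estimate.se / estimate.p_hat
    return cv if decimals is None else round(cv, decimals)


def classify_precision(
    estimates,
    cv_max: float = 20.0,
    deff_soft: float = 1.5,
    deff_hard: float = 2.0,
) -> dict[str, int]:
    """Count estimates meeting the survey-evaluation criteria.

    ``cv_pass``: Cv-p below cv_max (percent); ``deff_le_soft``: deff at
    most deff_soft; ``deff_lt_hard``: deff below deff_hard.  NaN
    diagnostics (degenerate estimates, se = 0 cases count via cv = 0)
    never pass a criterion they are undefined for — except that an exact
    se = 0 gives cv = 0 and deff = 0, which pass everything.
    """
    ests = list(estimates)
    if not ests:
        raise ValueError("no estimates to classify")
    cv_pass = deff_soft_pass = deff_hard_pass = 0
    for e in ests:
        cv = e.cv if not math.isnan(e.cv) else (0.0 if e.se == 0 else float("nan"))
        deff = e.deff if not math.isnan(e.deff) else (0.0 if e.se == 0 else float("nan"))
        if not math.isnan(cv) and cv < cv_max:
            cv_pass += 1
        if not math.isnan(deff):
            if deff <= deff_soft:
                deff_soft_pass += 1
            if deff < deff_hard:
                deff_hard_pass += 1
    return {
        "n_estimates": len(ests),
        "cv_pass": cv_pass,
        "deff_le_soft": deff_soft_pass,
        "deff_lt_hard": deff_hard_pass,
    }


def estimates_to_frame(estimates) -> pd.DataFrame:
    """Flat table of estimates (report/CSV form)."""
    return pd.DataFrame([e.to_dict() for e in estimates])
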