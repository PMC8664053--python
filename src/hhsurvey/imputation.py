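"""Predictive mean matching imputation.

PMM fills a missing value with an *observed* value borrowed from a donor
whose model-predicted value is closest to the recipient's prediction: a
linear predictor is fit on complete rows, predictions are computed for all
rows, and each missing row receives the observed target of one of its k
nearest-predicted donors, chosen uniformly at random.  Because imputed
values are always observed values, they stay in the target's support —
binary stays binary.

The procedure refuses to run when more than ``max_missing`` (default 20%)
of the target is missing: beyond that, matching on a single linear
predictor is too strong an assumption to patch silently.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import rng_from

__all__ = ["pmm_impute"]


class ImputationError(ValueError):
    """PMM preconditions not met."""


def pmm_impute(
    data: pd.DataFrame,
    target: str,
    predictors,
    k: int = 5,
    seed=None,
    max_missing: float = 0.20,
) -> pd.DataFrame:
    """Return a copy of ``data`` with missing ``target`` values imputed.

    ``predictors`` are numeric columns used in the linear predictor (an
    intercept is added).  Rows with missing predictor values cannot be
    matched and raise.
    """
    predictors = list(predictors)
    if target not in data.columns:
        raise ImputationError(f"unknown target {target!r}")
    y = data[target].to_numpy(dtype=float)
    miss = np.isnan(y)
    if not miss.any():
        return data.copy()

    frac = miss.mean()
    if frac > max_missing:
        raise ImputationError(
            f"{100 * frac:.1f}% of {target!r} is missing, above the "
            f"{100 * max_missing:.0f}% ceiling for predictive mean matching"
        )

    X = data[predictors].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ImputationError("predictors contain missing values")
    X1 = np.column_stack([np.ones(len(X)), X])

    donors = ~miss
    if donors.sum() < k:
        raise ImputationError(f"need at least k={k} complete donor rows")

    beta, *_ = np.linalg.lstsq(X1[donors], y[donors], rcond=None)
    pred = X1 @ beta

    rng = rng_from(seed)
    donor_pred = pred[donors]
    donor_y = y[donors]
    out_y = y.copy()
    kk = min(k, donors.sum())
    for i in np.flatnonzero(miss):
        d = np.abs(donor_pred - pred[i])
        nearest = np.argpartition(d, kk - 1)[:kk]
        out_y[i] = donor_y[rng.choice(nearest)]

    out = data.copy()
    out[target] = out_y
    return out
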