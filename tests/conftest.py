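"""Shared fixtures and independent oracles.

Oracles here are deliberately naive re-derivations (explicit loops, moment
estimators) kept independent of the library's vectorized implementations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hhsurvey import FrameConfig, IndicatorSpec, generate_frame


def anova_icc(values, groups) -> float:
    """One-way ANOVA (moment) estimator of the intra-cluster correlation.

    Standard unequal-cluster-size form: with MSB/MSW the between/within
    mean squares and n0 the effective cluster size,
    rho_hat = (MSB - MSW) / (MSB + (n0 - 1) MSW).
    """
    df = pd.DataFrame({"y": np.asarray(values, float), "g": groups}).dropna()
    k = df["g"].nunique()
    ni = df.groupby("g").size().to_numpy(dtype=float)
    N = ni.sum()
    means = df.groupby("g")["y"].mean().to_numpy()
    grand = df["y"].mean()
    ssb = float((ni * (means - grand) ** 2).sum())
    ssw = float(((df["y"] - df.groupby("g")["y"].transform("mean")) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - (ni**2).sum() / N) / (k - 1)
    return (msb - msw) / (msb + (n0 - 1) * msw)


def ultimate_cluster_variance_bruteforce(rows) -> tuple[float, float]:
    """Term-by-term evaluation of the linearized ratio variance.

    ``rows`` is an iterable of (psu_id, weight, y).  Returns (p_hat, var),
    computed with explicit loops straight from the formula: z_i = sum over
    PSU i of w*(y - p_hat)/W, v = m/(m-1) * sum_i (z_i - z_bar)^2, all
    PSUs retained.
    """
    rows = list(rows)
    W = sum(w for _, w, y in rows if y is not None)
    Y = sum(w * y for _, w, y in rows if y is not None)
    p_hat = Y / W
    psu_ids = []
    for g, _, _ in rows:
        if g not in psu_ids:
            psu_ids.append(g)
    z = {}
    for g in psu_ids:
        z[g] = sum(
            w * (y - p_hat) / W for gg, w, y in rows if gg == g and y is not None
        )
    m = len(psu_ids)
    zbar = sum(z.values()) / m
    var = m / (m - 1) * sum((zi - zbar) ** 2 for zi in z.values())
    return p_hat, var


@pytest.fixture(scope="session")
def small_frame():
    """A compact synthetic municipality with one correlated indicator."""
    cfg = FrameConfig(
        n_tracts=15,
        mean_households_per_tract=60,
        mean_persons_per_household=3.0,
        indicator_specs=[
            IndicatorSpec("health_ok", prevalence=0.3, icc=0.03),
            IndicatorSpec("uses_service", prevalence=0.6, icc=0.0, missing_rate=0.1),
        ],
        seed=42,
    )
    return generate_frame(cfg)


@pytest.fixture(scope="session")
def tiny_survey():
    """A hand-sized survey dataset: 3 PSUs x 4 persons with fixed values."""
    rows = [
        # psu, weight, y
        ("A", 2.0, 1.0), ("A", 2.0, 0.0), ("A", 1.5, 1.0), ("A", 1.0, 0.0),
        ("B", 2.0, 1.0), ("B", 2.5, 1.0), ("B", 1.0, 0.0), ("B", 1.0, 1.0),
        ("C", 1.0, 0.0), ("C", 2.0, 0.0), ("C", 2.0, 1.0), ("C", 3.0, 0.0),
    ]
    df = pd.DataFrame(rows, columns=["psu_id", "weight", "y"])
    return df, rows
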