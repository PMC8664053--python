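"""Two-stage systematic PPS sampling of households.

First stage: from the code-ordered PSU list, a systematic sample of ``a``
PSUs with probability proportional to size (household count M_i): sizes are
cumulated, the selection interval is I = sum(M_i)/a, a uniform real start
U ~ [0, I) is drawn and the PSUs containing the points U, U+I, ...,
U+(a-1)I are selected.  First-stage inclusion probability: pi_i = a*M_i /
sum(M_i) (a PSU with M_i > I may be hit more than once — a certainty unit;
its probability is capped at 1 and a warning is emitted).

Second stage: within each selected PSU, a systematic sample of households.
The planned take ``b`` defines a fixed second-stage fraction b/M_i; applied
to the updated field listing M_i' it yields round(b * M_i'/M_i) households,
so the realized take grows or shrinks with the frame.  With M_i' = M_i the
overall inclusion probability of every household is the constant global
fraction

    f = a * M_i/sum(M_i) * b/M_i = a * b / sum(M_i)

— a self-weighting design with design weight 1/f.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import round_half_up, rng_from

__all__ = [
    "systematic_sample",
    "systematic_pps_select",
    "second_stage_count",
    "inclusion_probabilities",
    "draw_sample",
    "SampleDraw",
]


class CertaintySelectionWarning(UserWarning):
    """A PSU larger than the selection interval is selected with certainty."""


class EmptyListingWarning(UserWarning):
    """A selected PSU's field listing contains no households."""


def systematic_sample(n_units: int, k: int, seed=None) -> np.ndarray:
    """Positions of a systematic sample of k out of n ordered units.

    Fractional-interval systematic sampling: interval = n/k, real random
    start in [0, interval), positions floor(start + j*interval).  All k
    positions are distinct and every unit's inclusion probability is k/n.
    """
    if k < 0 or k > n_units:
        raise ValueError(f"cannot draw {k} of {n_units} units")
    if k == 0:
        return np.array([], dtype=int)
    rng = rng_from(seed)
    interval = n_units / k
    start = rng.uniform(0.0, interval)
    pos = np.floor(start + interval * np.arange(k)).astype(int)
    return np.minimum(pos, n_units - 1)


def systematic_pps_select(psus, a: int, seed=None) -> list:
    """Systematic PPS selection of ``a`` PSUs from the code-ordered list.

    Returns the selected PSUs in list order; a certainty unit (M_i larger
    than the interval) may appear more than once, with a warning.
    """
    psus = list(psus)
    if a < 1 or a > len(psus):
        raise ValueError(f"cannot select {a} of {len(psus)} PSUs")
    sizes = np.array([p.M for p in psus], dtype=float)
    if (sizes <= 0).any():
        raise ValueError("every PSU must have M > 0")
    total = sizes.sum()
    interval = total / a
    if (sizes > interval).any():
        warnings.warn(
            "PSU(s) larger than the selection interval are certainty "
            "selections (pi capped at 1)",
            CertaintySelectionWarning,
            stacklevel=2,
        )
    rng = rng_from(seed)
    points = rng.uniform(0.0, interval) + interval * np.arange(a)
    cum = np.cumsum(sizes)
    idx = np.searchsorted(cum, points, side="right")
    return [psus[i] for i in idx]


def first_stage_probabilities(psus, a: int) -> np.ndarray:
    """pi_i = a * M_i / sum(M_i), capped at 1 for certainty units."""
    sizes = np.array([p.M for p in psus], dtype=float)
    return np.minimum(a * sizes / sizes.sum(), 1.0)


def second_stage_count(b: int, M_i: int, M_i_prime: int) -> int:
    """Households to draw in a PSU whose listing found M_i' households.

    The fixed design fraction b/M_i applied to the updated listing:
    round-to-nearest of b * M_i'/M_i.
    """
    if M_i <= 0:
        raise ValueError("design household count M_i must be positive")
    if M_i_prime < 0:
        raise ValueError("listing count cannot be negative")
    if M_i_prime == 0:
        warnings.warn(
            "selected PSU has an empty field listing; drawing 0 households",
            EmptyListingWarning,
            stacklevel=2,
        )
        return 0
    return round_half_up(b * M_i_prime / M_i)


@dataclass
class SampleDraw:
    """Result of one two-stage draw.

    ``households`` carries one row per selected household (household_id,
    psu_id, first/second stage probabilities, overall probability, design
    weight).  ``f`` is the global sampling fraction a*b/sum(M_i).
    """

    a: int
    b: int
    f: float
    total_M: int
    selected: pd.DataFrame        # per selected PSU: psu_id, M, M_prime, b_i, pi_i
    households: pd.DataFrame
    seed: int | None = None
    warnings: list[str] = field(default_factory=list)

    def manifest(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "f": self.f,
            "total_M": self.total_M,
            "n_selected_psus": int(len(self.selected)),
            "n_households_drawn": int(len(self.households)),
            "seed": self.seed,
            "warnings": list(self.warnings),
        }


def inclusion_probabilities(draw: SampleDraw) -> pd.DataFrame:
    """Per-household overall inclusion probability for a draw.

    In the design-frame case (M_i' = M_i for every selected PSU) the
    overall probability is the constant f = a*b/sum(M_i) for every
    household — the self-weighting property.
    """
    out = draw.households.loc[
        :, ["household_id", "psu_id", "pi_psu", "p_second", "p_overall", "weight"]
    ].copy()
    return out


def draw_sample(
    psus,
    households: pd.DataFrame,
    a: int,
    b: int,
    seed=None,
) -> SampleDraw:
    """Execute the full two-stage draw.

    ``households`` must carry a ``psu_id`` column (see
    :func:`hhsurvey.psu.assign_households`); household order within a PSU
    is the frame listing order used by the second-stage systematic pass.
    PSUs whose ``M_prime`` differs from ``M`` are sampled at the fixed
    fraction b/M_i applied to the actual listing rows present.
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    psus = list(psus)
    rng = rng_from(seed)
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        chosen = systematic_pps_select(psus, a, rng)
        total_M = int(sum(p.M for p in psus))
        f = a * b / total_M

        by_psu = dict(tuple(households.groupby("psu_id", sort=False)))
        sel_rows = []
        hh_parts = []
        for p in chosen:
            listing = by_psu.get(p.psu_id)
            m_listed = 0 if listing is None else len(listing)
            b_i = second_stage_count(b, p.M, p.listing if p.M_prime is not None else m_listed)
            b_i = min(b_i, m_listed)
            pi_i = min(a * p.M / total_M, 1.0)
            sel_rows.append(
                {
                    "psu_id": p.psu_id, "M": p.M, "M_prime": p.listing,
                    "b_i": b_i, "pi_i": pi_i,
                }
            )
            if b_i == 0 or listing is None:
                continue
            pos = systematic_sample(m_listed, b_i, rng)
            part = listing.iloc[pos].copy()
            part["pi_psu"] = pi_i
            part["p_second"] = b_i / m_listed
            hh_parts.append(part)
        for w in wlist:
            caught.append(str(w.message))

    hh = (
        pd.concat(hh_parts, ignore_index=True)
        if hh_parts
        else households.iloc[0:0].assign(pi_psu=[], p_second=[])
    )
    if len(hh):
        hh["p_overall"] = hh["pi_psu"] * hh["p_second"]
        hh["weight"] = 1.0 / hh["p_overall"]
    selected = pd.DataFrame(sel_rows)
    return SampleDraw(
        a=a, b=b, f=f, total_M=total_M, selected=selected, households=hh,
        seed=None if isinstance(seed, np.random.Generator) else seed,
        warnings=caught,
    )
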