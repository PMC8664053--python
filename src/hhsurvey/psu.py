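"""Primary Sampling Unit construction from census tracts.

PSUs are area units assembled from census tracts so their household counts
are homogeneous: a PSU may be a single tract, a fraction of a tract, or a
grouping of consecutive tracts (by tract code), and the coefficient of
variation of PSU sizes must not exceed a threshold (10% by default).
Homogeneous sizes make the later systematic PPS draw nearly equal
probability and keep the self-weighting design efficient.

Algorithm: with T the mean tract size, any unit larger than 1.5*T is split
into ceil(size / T) near-equal fractions (whole households, largest
remainder); consecutive units smaller than 0.5*T are greedily merged with
their successor.  Passes repeat until the size CV meets the threshold.  If
a pass changes nothing and the CV still exceeds the threshold (moderate
dispersion with no unit beyond the split/merge triggers), a final rebalance
cuts the code-ordered household sequence into near-equal consecutive
chunks — the same divide-and-group vocabulary taken to completion.
Construction fails with diagnostics only if even that cannot meet the
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PSU", "build_psus", "size_cv", "assign_households", "psus_to_frame"]


@dataclass(frozen=True)
class PSU:
    """An area unit: one tract, a tract fraction, or grouped tracts.

    ``members`` is a tuple of (tract_id, fraction, household_count); the
    fractions of any one tract across all PSUs sum to at most 1.  ``M`` is
    the design-frame household count; ``M_prime`` the updated count from a
    field listing (equal to M until a listing is recorded).
    """

    psu_id: str
    members: tuple[tuple[str, float, int], ...]
    M: int
    M_prime: int | None = None

    @property
    def listing(self) -> int:
        return self.M if self.M_prime is None else self.M_prime

    def with_listing(self, m_prime: int) -> "PSU":
        return PSU(self.psu_id, self.members, self.M, m_prime)


class PSUConstructionError(RuntimeError):
    """Size homogenisation could not reach the requested CV."""


def size_cv(psus) -> float:
    """Coefficient of variation of PSU sizes: population SD of M over mean M."""
    sizes = np.array([p.M for p in psus], dtype=float)
    if sizes.size < 2:
        raise ValueError("size_cv needs at least 2 PSUs")
    mean = sizes.mean()
    if mean == 0:
        raise ValueError("all PSUs are empty")
    return float(sizes.std(ddof=0) / mean)


def _split_counts(total: int, parts: int) -> list[int]:
    """Split ``total`` households into ``parts`` near-equal whole counts."""
    base = total // parts
    rem = total - base * parts
    return [base + 1] * rem + [base] * (parts - rem)


def _rebalance(
    work: pd.DataFrame, n_units: int
) -> list[list[tuple[str, float, int]]]:
    """Cut the code-ordered household sequence into near-equal chunks.

    Tracts are consumed in code order; a tract straddling a chunk boundary
    is split into fractions (whole households).  Chunk sizes differ by at
    most one household.
    """
    total = int(work["n_households"].sum())
    n_units = max(2, min(n_units, total))
    targets = _split_counts(total, n_units)
    units: list[list[tuple[str, float, int]]] = []
    current: list[tuple[str, float, int]] = []
    room = targets[0]
    ui = 0
    for t in work.itertuples():
        remaining = int(t.n_households)
        while remaining > 0:
            take = min(remaining, room)
            current.append((t.tract_id, take / t.n_households, take))
            remaining -= take
            room -= take
            if room == 0 and ui < n_units - 1:
                units.append(current)
                current = []
                ui += 1
                room = targets[ui]
    if current:
        units.append(current)
    return units


def build_psus(tracts: pd.DataFrame, cv_max: float = 0.10, max_passes: int = 50) -> list[PSU]:
    """Assemble PSUs from a tract table (tract_id, n_households).

    Tracts are processed in tract-code order and the resulting PSUs are
    ordered by the code of their first member, preserving the geographic
    ordering the systematic draw relies on.  Every household of every tract
    belongs to exactly one PSU.
    """
    work = tracts.loc[tracts["n_households"] > 0, ["tract_id", "n_households"]]
    if work.empty:
        raise ValueError("no tract with households")
    work = work.sort_values("tract_id")

    # units: list of member-lists; a member is (tract_id, fraction, count)
    units: list[list[tuple[str, float, int]]] = [
        [(t.tract_id, 1.0, int(t.n_households))] for t in work.itertuples()
    ]

    def usize(u):
        return sum(c for _, _, c in u)

    for _ in range(max_passes):
        sizes = np.array([usize(u) for u in units], dtype=float)
        if sizes.size >= 2 and sizes.std(ddof=0) / sizes.mean() <= cv_max:
            break
        if sizes.size == 1:
            break
        T = sizes.mean()
        changed = False

        split: list[list[tuple[str, float, int]]] = []
        for u in units:
            s = usize(u)
            if s > 1.5 * T and len(u) == 1 and s >= 2:
                tract_id, frac, count = u[0]
                parts = math.ceil(s / T)
                parts = min(parts, count)
                if parts >= 2:
                    for c in _split_counts(count, parts):
                        split.append([(tract_id, frac * c / count, c)])
                    changed = True
                    continue
            split.append(u)
        units = split

        merged: list[list[tuple[str, float, int]]] = []
        T = np.mean([usize(u) for u in units])
        i = 0
        while i < len(units):
            u = units[i]
            if usize(u) < 0.5 * T and i + 1 < len(units):
                units[i + 1] = u + units[i + 1]
                changed = True
            else:
                merged.append(u)
            i += 1
        units = merged

        if not changed:
            sizes = np.array([usize(u) for u in units], dtype=float)
            cv = sizes.std(ddof=0) / sizes.mean() if sizes.size > 1 else 0.0
            if sizes.size >= 2 and cv > cv_max:
                units = _rebalance(work, len(units))
                sizes = np.array([usize(u) for u in units], dtype=float)
                cv = sizes.std(ddof=0) / sizes.mean()
                if cv > cv_max:
                    raise PSUConstructionError(
                        f"size CV {cv:.3f} > {cv_max} even after rebalancing; "
                        f"sizes min={sizes.min():.0f} max={sizes.max():.0f} "
                        f"over {sizes.size} units"
                    )
            break

    width = max(4, len(str(len(units))))
    psus = [
        PSU(
            psu_id=f"U{i:0{width}d}",
            members=tuple(u),
            M=usize(u),
        )
        for i, u in enumerate(sorted(units, key=lambda u: u[0][0]), start=1)
    ]
    total_in = int(work["n_households"].sum())
    total_out = sum(p.M for p in psus)
    assert total_in == total_out, "household conservation violated"
    if len(psus) >= 2 and size_cv(psus) > cv_max:
        raise PSUConstructionError(
            f"size CV {size_cv(psus):.3f} exceeds {cv_max} after {max_passes} passes"
        )
    return psus


def assign_households(psus, households: pd.DataFrame) -> pd.DataFrame:
    """Attach a psu_id to every household row.

    Households of a tract are assigned to that tract's PSU fractions in
    household order, matching the whole-household counts recorded in each
    PSU's members — deterministic and conservative (each household lands in
    exactly one PSU).
    """
    alloc: dict[str, list[tuple[str, int]]] = {}
    for p in psus:
        for tract_id, _, count in p.members:
            alloc.setdefault(tract_id, []).append((p.psu_id, count))

    out = households.copy()
    labels = np.empty(len(out), dtype=object)
    positions = out.groupby("tract_id", sort=False).indices
    for tract_id, pos in positions.items():
        pieces = alloc.get(tract_id)
        if pieces is None:
            raise KeyError(f"tract {tract_id} has no PSU assignment")
        start = 0
        for psu_id, count in pieces:
            labels[pos[start : start + count]] = psu_id
            start += count
        if start != len(pos):
            raise ValueError(
                f"tract {tract_id}: {len(pos)} households but PSU members "
                f"account for {start}"
            )
    out["psu_id"] = labels
    return out


def psus_to_frame(psus) -> pd.DataFrame:
    """Flat table view of a PSU list (one row per PSU)."""
    return pd.DataFrame(
        {
            "psu_id": [p.psu_id for p in psus],
            "M": [p.M for p in psus],
            "M_prime": [p.listing for p in psus],
            "members": [
                ";".join(f"{t}:{f:.6g}" for t, f, _ in p.members) for p in psus
            ],
        }
    )
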