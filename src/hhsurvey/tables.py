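"""Packaged census inputs: stratum populations and municipal household totals.

The 2010 census counts for the two study municipalities (population per
sex × age-group stratum, and the number of private households) are the
published inputs the sample-size methodology starts from; they ship with
the package so the planning arithmetic is reproducible offline.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

__all__ = ["load_stratum_populations", "load_household_totals"]


def _data_path(name: str):
    return resources.files("hhsurvey.data").joinpath(name)


def load_stratum_populations(municipality: str | None = None) -> pd.DataFrame:
    """Census population per municipality × sex × age group.

    Returns a DataFrame with columns ``municipality, sex, age_group, N``.
    If *municipality* is given, rows are filtered to it.
    """
    with resources.as_file(_data_path("census_strata.csv")) as p:
        df = pd.read_csv(p, dtype={"sex": str, "age_group": str})
    if municipality is not None:
        df = df[df["municipality"] == municipality].reset_index(drop=True)
        if df.empty:
            raise KeyError(f"unknown municipality: {municipality!r}")
    return df


def load_household_totals() -> dict[str, int]:
    """Number of private households per municipality (census frame)."""
    with resources.as_file(_data_path("household_totals.json")) as p:
        return {k: int(v) for k, v in json.loads(p.read_text()).items()}
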