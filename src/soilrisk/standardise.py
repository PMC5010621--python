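"""Indirect standardisation: expected deaths from reference rates.

Expected cases per municipality are computed by taking stratum-specific
reference rates (18 age groups x 2 sexes x 2 five-year periods) and
multiplying them by the town's person-years in the same strata; person-years
per quinquennium are the mid-period population times 5.  With rates derived
internally from the study universe itself, the construction conserves
totals: sum of expected equals sum of observed deaths per sex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .universe import AGE_GROUPS, PERIODS, SEXES

logger = logging.getLogger(__name__)

N_STRATA = len(AGE_GROUPS) * len(SEXES) * len(PERIODS)  # 18 x 2 x 2 = 72


@dataclass
class RateTable:
    """Reference mortality rates (deaths per person-year) by stratum.

    ``table`` is indexed by (age_group, sex, period) and must cover exactly
    the 18 x 2 x 2 stratification.
    """

    table: pd.Series

    def __post_init__(self) -> None:
        expected_index = pd.MultiIndex.from_product(
            [AGE_GROUPS, SEXES, PERIODS], names=["age_group", "sex", "period"]
        )
        if len(self.table) != N_STRATA or not set(self.table.index) == set(expected_index):
            raise ValueError(
                f"rate table must have exactly {N_STRATA} strata "
                "(18 age groups x 2 sexes x 2 periods)"
            )
        if (self.table < 0).any():
            raise ValueError("rates must be >= 0")

    @classmethod
    def from_schedule(cls, age_rates) -> "RateTable":
        """Build a table from an 18-vector of age-specific rates, shared
        across sexes and periods."""
        age_rates = np.asarray(age_rates, dtype=float)
        idx = pd.MultiIndex.from_product(
            [AGE_GROUPS, SEXES, PERIODS], names=["age_group", "sex", "period"]
        )
        vals = np.repeat(age_rates, len(SEXES) * len(PERIODS))
        return cls(pd.Series(vals, index=idx, name="rate"))

    def lookup(self, strata: pd.DataFrame) -> np.ndarray:
        """Rates aligned to the rows of a long-format strata table."""
        key = pd.MultiIndex.from_frame(strata[["age_group", "sex", "period"]])
        missing = set(key) - set(self.table.index)
        if missing:
            raise KeyError(f"rate table is missing strata: {sorted(missing)[:5]}")
        return self.table.reindex(key).to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return self.table.rename("rate").reset_index()


def person_years(strata: pd.DataFrame) -> pd.Series:
    """Person-years per stratum row: mid-period population x 5."""
    pop = strata["population"]
    if (pop < 0).any():
        raise ValueError("populations must be >= 0")
    return pop * 5.0


def national_rates(strata: pd.DataFrame) -> RateTable:
    """Pooled stratum-specific rates over all areas of the study.

    rate(stratum) = total deaths / total person-years in that stratum.
    Strata with zero person-years get rate 0 with a logged warning.
    """
    df = strata.copy()
    df["py"] = person_years(df)
    agg = df.groupby(["age_group", "sex", "period"], sort=False)[["deaths", "py"]].sum()
    if not (agg["py"] > 0).any():
        raise ValueError("all strata have zero person-years")
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(agg["py"] > 0, agg["deaths"] / agg["py"], 0.0)
    n_empty = int((agg["py"] <= 0).sum())
    if n_empty:
        logger.warning("%d strata have zero person-years; their rates set to 0", n_empty)
    full_idx = pd.MultiIndex.from_product(
        [AGE_GROUPS, SEXES, PERIODS], names=["age_group", "sex", "period"]
    )
    series = pd.Series(rate, index=agg.index).reindex(full_idx, fill_value=0.0)
    return RateTable(series)


def expected_cases(strata: pd.DataFrame, rates: RateTable) -> pd.DataFrame:
    """Expected deaths per area and sex: sum over strata of rate x person-years.

    Returns a wide table with columns ``area_id`` and one column per sex.
    """
    df = strata.copy()
    df["py"] = person_years(df)
    df["e"] = rates.lookup(df) * df["py"]
    wide = (
        df.groupby(["area_id", "sex"], sort=False)["e"].sum().unstack("sex").reset_index()
    )
    for sex in SEXES:
        if sex not in wide:
            wide[sex] = 0.0
    return wide[["area_id", *SEXES]]


def attach_expected(areas: pd.DataFrame, strata: pd.DataFrame) -> pd.DataFrame:
    """Attach internally standardised expected deaths to the area table."""
    rates = national_rates(strata)
    exp_df = expected_cases(strata, rates).set_index("area_id")
    areas = areas.copy()
    for sex in SEXES:
        areas[f"expected_{sex}"] = exp_df.loc[areas["area_id"], sex].to_numpy()
    return areas
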