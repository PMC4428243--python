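"""Indirect standardization: expected deaths, SMRs, and count suppression.

Mortality arrives as a stratified table — one row per county × stratum
(gender × 10-year age band) with the population at risk and the death count
over the study period.  Standard rates are the pooled national stratum
rates; a county's expected count is the deaths it would see if its
population experienced the standard rates, and its standardized mortality
ratio (SMR) is observed/expected.  Counties whose observed county total is
0–9 deaths are suppressed (confidentiality rule) and excluded from all
downstream modelling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SUPPRESSION_MAX",
    "validate_table",
    "standard_rates",
    "expected_deaths",
    "observed_deaths",
    "smr_with_suppression",
    "smr_table",
]

SUPPRESSION_MAX = 9  # county totals of 0..9 deaths are suppressed

TABLE_COLUMNS = ["county_id", "stratum_id", "population", "deaths"]


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a stratified mortality table and coerce dtypes."""
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"mortality table missing columns: {missing}")
    t = table.copy()
    t["population"] = t["population"].astype(float)
    t["deaths"] = t["deaths"].astype(float)
    if (t["deaths"] < 0).any() or (t["population"] < 0).any():
        raise ValueError("deaths and population must be non-negative")
    if (t["deaths"] > t["population"]).any():
        raise ValueError("deaths cannot exceed population in a stratum")
    return t


def standard_rates(table: pd.DataFrame) -> pd.Series:
    """Pooled national rate per stratum: Σ deaths / Σ population.

    In closure mode the standard population is the aggregate of the study
    counties themselves, so total expected equals total observed exactly.
    """
    t = validate_table(table)
    g = t.groupby("stratum_id", sort=True)[["deaths", "population"]].sum()
    if (g["population"] <= 0).any():
        bad = g.index[g["population"] <= 0].tolist()
        raise ValueError(f"zero total population in strata {bad}")
    rates = g["deaths"] / g["population"]
    rates.name = "rate"
    return rates


def expected_deaths(table: pd.DataFrame, rates: pd.Series) -> pd.Series:
    """Per-county expected deaths E_i = Σ_s population_is · rate_s."""
    t = validate_table(table)
    strata = set(t["stratum_id"].unique())
    known = set(rates.index)
    if not strata <= known:
        raise ValueError(f"missing standard rates for strata {sorted(strata - known)}")
    t = t.assign(expected=t["population"].to_numpy()
                 * rates.reindex(t["stratum_id"]).to_numpy())
    e = t.groupby("county_id", sort=True)["expected"].sum()
    e.name = "expected"
    return e


def observed_deaths(table: pd.DataFrame) -> pd.Series:
    """Per-county observed death totals."""
    t = validate_table(table)
    o = t.groupby("county_id", sort=True)["deaths"].sum()
    o.name = "observed"
    return o


def smr_with_suppression(observed: pd.Series, expected: pd.Series,
                         suppression_max: int = SUPPRESSION_MAX) -> pd.DataFrame:
    """SMR = observed/expected with the 0–9 suppression rule applied.

    Counties with observed totals ≤ ``suppression_max`` are marked
    suppressed; their SMR is reported as NaN and they are to be excluded
    from spatial analysis and regression.  Returns a DataFrame with columns
    county_id, observed, expected, smr, suppressed.
    """
    observed = pd.Series(observed)
    expected = pd.Series(expected)
    if not observed.index.equals(expected.index):
        expected = expected.reindex(observed.index)
        if expected.isna().any():
            raise ValueError("expected counts missing for some counties")
    obs = observed.to_numpy(dtype=float)
    exp = expected.to_numpy(dtype=float)
    if np.any((exp <= 0) & (obs > 0)):
        raise ValueError("expected = 0 with observed > 0: inconsistent table")
    suppressed = obs <= suppression_max
    with np.errstate(divide="ignore", invalid="ignore"):
        smr = np.where(exp > 0, obs / exp, np.nan)
    smr = np.where(suppressed, np.nan, smr)
    return pd.DataFrame({
        "county_id": observed.index.astype(str),
        "observed": obs,
        "expected": exp,
        "smr": smr,
        "suppressed": suppressed,
    }).reset_index(drop=True)


def smr_table(table: pd.DataFrame,
              rates: pd.Series | None = None,
              suppression_max: int = SUPPRESSION_MAX) -> pd.DataFrame:
    """Convenience chain: rates (closure mode if omitted) → E_i → SMR."""
    if rates is None:
        rates = standard_rates(table)
    e = expected_deaths(table, rates)
    o = observed_deaths(table)
    return smr_with_suppression(o, e, suppression_max=suppression_max)
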