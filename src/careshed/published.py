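"""Published national accessibility tables for Ireland, Spain and Switzerland.

The three-country palliative-care accessibility study printed population
counts per fine driving-time interval (0-10 ... 60-90, over 90) nationally,
and 0-30 / 30-60 / over-60 counts per region. These printed counts are
*inputs* here: the tabulation operations re-derive the subtotals and
percentages from them, which is how the arithmetic of :mod:`careshed.tabulation`
is exercised against independently published numbers.

Two printing quirks of the source tables worth knowing (kept as printed, not
reconciled): a few national subtotals differ by one person from the sum of
their printed intervals (the source rounded real-valued allocations row by
row), and Spain's national total differs slightly between the interval table
and the regional table.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from careshed._util import Interval, parse_interval_label

COUNTRIES = ("Ireland", "Spain", "Switzerland")
_REGION_FILES = {
    "Ireland": "regions_ireland.csv",
    "Spain": "regions_spain.csv",
    "Switzerland": "regions_switzerland.csv",
}


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("careshed").joinpath("data/published").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_country_intervals() -> pd.DataFrame:
    """Fine-interval national counts: columns country, interval, population."""
    return _read("country_intervals.csv")


def country_interval_counts(country: str) -> dict[Interval, float]:
    """Printed fine-interval counts of one country keyed by (lo, hi]."""
    df = load_country_intervals()
    sel = df[df["country"] == country]
    if sel.empty:
        raise KeyError(f"no published table for {country!r}")
    return {
        parse_interval_label(row.interval): float(row.population)
        for row in sel.itertuples()
    }


def load_country_subtotals() -> pd.DataFrame:
    """Printed 0-30 / 30-60 / over-60 subtotals and percentages per country."""
    return _read("country_subtotals.csv")


def load_country_totals() -> pd.DataFrame:
    """Printed national grand totals."""
    return _read("country_totals.csv")


def load_regional_table(country: str) -> pd.DataFrame:
    """Printed regional band counts and percentages for one country.

    Columns: region, n_0_30, pct_0_30, n_30_60, pct_30_60, n_over_60,
    pct_over_60, total. The final row is the national summary.
    """
    if country not in _REGION_FILES:
        raise KeyError(f"no regional table for {country!r}")
    return _read(_REGION_FILES[country])
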