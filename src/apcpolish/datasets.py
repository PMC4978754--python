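"""Packaged example data.

The packaged table is the published age-period contingency table of US
motorcycle-crash mortality rates per 100,000 population, 1975-2014: fourteen
five-year age groups (15-19 through 80-84) by eight five-year periods
(1975-1979 through 2010-2014), spanning 21 birth cohorts (1895-1899 through
1995-1999).
"""

from importlib import resources

from .rate_table import RateTable

_FILENAME = "us_motorcycle_mortality_1975_2014.csv"


def load_motorcycle_rates() -> RateTable:
    """US motorcycle-crash mortality rates, 14 age groups x 8 periods."""
    ref = resources.files("apcpolish.data").joinpath(_FILENAME)
    with resources.as_file(ref) as path:
        return RateTable.read_csv(path, label="all")
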