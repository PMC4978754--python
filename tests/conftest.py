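import numpy as np
import pytest

from apcpolish import AgeBin, PeriodBin, RateTable, load_motorcycle_rates


@pytest.fixture(scope="session")
def table1() -> RateTable:
    """The packaged US motorcycle mortality table (14 ages x 8 periods)."""
    return load_motorcycle_rates()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


def make_random_table(rng, n_ages=4, n_periods=5, low=0.1, high=10.0) -> RateTable:
    rates = rng.uniform(low, high, size=(n_ages, n_periods))
    return RateTable(
        ages=tuple(AgeBin(start=15 + 5 * i) for i in range(n_ages)),
        periods=tuple(PeriodBin(start=1975 + 5 * j) for j in range(n_periods)),
        rates=rates,
    )


# Printed rate ratios and 95% CIs for the cohort effects, reference
# 1930-1934, oldest cohort first (the published Table 2 of the study the
# packaged fixture comes from).
PUBLISHED_RATE_RATIOS = {
    "1895–1899": (0.66, 0.29, 1.50),
    "1900–1904": (0.95, 0.51, 1.75),
    "1905–1909": (0.97, 0.58, 1.64),
    "1910–1914": (0.69, 0.43, 1.11),
    "1915–1919": (0.91, 0.59, 1.42),
    "1920–1924": (0.92, 0.60, 1.39),
    "1925–1929": (0.78, 0.53, 1.17),
    "1930–1934": (1.00, None, None),
    "1935–1939": (1.15, 0.78, 1.69),
    "1940–1944": (1.27, 0.86, 1.87),
    "1945–1949": (1.43, 0.97, 2.10),
    "1950–1954": (1.47, 1.00, 2.16),
    "1955–1959": (1.48, 1.01, 2.18),
    "1960–1964": (1.47, 1.00, 2.17),
    "1965–1969": (1.17, 0.79, 1.75),
    "1970–1974": (0.96, 0.63, 1.46),
    "1975–1979": (0.69, 0.45, 1.08),
    "1980–1984": (0.46, 0.29, 0.74),
    "1985–1989": (0.39, 0.23, 0.65),
    "1990–1994": (0.28, 0.15, 0.51),
    "1995–1999": (0.17, 0.07, 0.38),
}

PUBLISHED_STARRED = {
    "1955–1959", "1960–1964", "1980–1984", "1985–1989", "1990–1994", "1995–1999",
}
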