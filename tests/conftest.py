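"""Shared fixtures: the Al-Ahsa 2022-2045 reference inputs and published
reference projections used across the suite.

Reference tables hold, per year, each quantity as (point, lower, upper)
integers after display rounding.
"""

from __future__ import annotations

import pytest

import draburden as d

# year -> (cases, total, major, minor, deaths_amp, deaths_nonamp); each
# quantity beyond cases is (point, lo, hi)
CONSTANT_TABLE = {
    2022: (54805, (129, 103, 154), (52, 42, 62), (77, 61, 92), (11, 9, 13), (1302, 1041, 1562)),
    2026: (63492, (149, 119, 179), (60, 48, 72), (89, 71, 107), (13, 10, 16), (1508, 1207, 1810)),
    2030: (72178, (169, 136, 203), (68, 55, 82), (101, 81, 121), (15, 12, 18), (1715, 1372, 2057)),
    2034: (78703, (185, 148, 222), (75, 60, 90), (110, 88, 132), (16, 13, 19), (1870, 1496, 2243)),
    2038: (85228, (200, 160, 240), (81, 65, 97), (119, 95, 143), (17, 14, 21), (2025, 1620, 2429)),
    2042: (91753, (215, 172, 259), (87, 70, 104), (128, 103, 154), (19, 15, 22), (2180, 1744, 2615)),
    2045: (96647, (227, 182, 272), (92, 73, 110), (135, 108, 162), (20, 16, 24), (2296, 1837, 2755)),
}

DECLINE_TABLE = {
    2022: (54805, (103, 82, 124), (42, 33, 50), (61, 49, 74), (9, 7, 11), (1302, 1042, 1563)),
    2026: (63492, (98, 78, 117), (36, 29, 43), (62, 49, 74), (8, 7, 10), (1509, 1208, 1811)),
    2030: (72178, (91, 73, 110), (30, 24, 36), (61, 49, 73), (8, 6, 10), (1716, 1373, 2060)),
    2034: (78703, (82, 66, 99), (24, 20, 29), (58, 46, 69), (7, 6, 9), (1872, 1498, 2246)),
    2038: (85228, (74, 59, 89), (20, 16, 24), (54, 44, 65), (6, 5, 8), (2028, 1622, 2433)),
    2042: (91753, (67, 53, 80), (16, 13, 19), (51, 41, 61), (6, 5, 7), (2183, 1746, 2620)),
    2045: (96647, (61, 49, 74), (13, 11, 16), (48, 39, 58), (5, 4, 6), (2300, 1840, 2760)),
}

QUANTITY_COLUMNS = ["total_dra", "major_dra", "minor_dra", "deaths_amp", "deaths_nonamp"]

OBSERVED_2022 = {"King Fahad Hospital": 73, "Prince Saud Bin Jalawi Hospital": 9}


@pytest.fixture(scope="session")
def alahsa_config() -> d.RunConfig:
    return d.load_config(d.packaged_config_path())


@pytest.fixture(scope="session")
def case_series(alahsa_config) -> d.CaseSeries:
    return d.build_case_series(
        alahsa_config.base_year,
        alahsa_config.base_count,
        alahsa_config.anchors,
        alahsa_config.final_year,
    )


@pytest.fixture(scope="session")
def rates(alahsa_config) -> d.TransitionRates:
    return alahsa_config.rates


@pytest.fixture(scope="session")
def constant_projection(case_series, rates) -> d.ProjectionSeries:
    return d.run_projection(case_series, rates)


@pytest.fixture(scope="session")
def decline_projection(alahsa_config, case_series, rates) -> d.ProjectionSeries:
    return d.run_projection(case_series, rates, alahsa_config.scenarios["mixed-decline"])


@pytest.fixture()
def observed_2022() -> d.ObservedCounts:
    return d.ObservedCounts(year=2022, facility_counts=OBSERVED_2022)
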