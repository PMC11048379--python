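import pytest
from hypothesis import HealthCheck, settings

from cidtherm.foldon import (
    GRID_SERIES_1,
    GRID_SERIES_2,
    STUDY_COURSE_PARAMS,
    foldon_ions,
    foldon_proteoforms,
)
from cidtherm.thermo import ThermoConfig

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Printed course characteristics (complex, initial, final, dcv50, dx, slope, r2)
TABLE2 = {
    "I": ("F-F-F", 98.78, 0.00, 17.03, 1.70, -14.54, 0.999),
    "II": ("F-F-bF", 99.64, 0.00, 16.93, 2.32, -10.74, 0.995),
    "III": ("F-bF-bF", 100.00, 0.00, 20.51, 2.95, -8.47, 0.999),
    "IV": ("bF-bF-bF", 100.00, 0.26, 19.57, 1.84, -13.55, 0.999),
}

#: Printed extrapolated quantities (complex, k 1/s, KD, dG, dH, TdS in kJ/mol)
TABLE3 = {
    "I": ("F-F-F", 2.17e7, 3.16e-12, 65.61, 3.32, -62.29),
    "II": ("F-F-bF", 9.16e8, 3.58e-12, 65.30, 1.86, -63.44),
    "III": ("F-bF-bF", 7.83e8, 3.62e-12, 65.27, 1.08, -64.19),
    "IV": ("bF-bF-bF", 8.68e6, 3.06e-12, 65.68, 3.85, -61.84),
}

#: Printed molecular-information rows: symbol -> (m/z calcd, z, atom number)
TABLE1 = {
    "F-F-F": (1848.75, 5, 1299),
    "F-F-bF": (1951.79, 5, 1371),
    "F-bF-bF": (2054.84, 5, 1443),
    "bF-bF-bF": (2157.89, 5, 1515),
    "F-F": (2054.05, 3, 866),
    "F-bF": (2225.79, 3, 938),
    "bF-bF": (2397.55, 3, 1010),
    "F": (1540.79, 2, 433),
    "bF": (1798.41, 2, 505),
}


@pytest.fixture(scope="session")
def proteoforms():
    return foldon_proteoforms()


@pytest.fixture(scope="session")
def ions():
    return foldon_ions()


@pytest.fixture(scope="session")
def cfg():
    return ThermoConfig()


@pytest.fixture(scope="session")
def study_grids():
    return GRID_SERIES_1, GRID_SERIES_2


@pytest.fixture(scope="session")
def course_params():
    return dict(STUDY_COURSE_PARAMS)
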