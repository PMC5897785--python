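"""Shared fixtures: the published m/z ladders and abundance statistics used
as ground truth throughout the suite."""

import hypothesis
import pytest

from nativekd import SpeciesDefinition
from nativekd.constants import DC2AC2_MASS, DC5_MASS, RNASE_A_MASS

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=100, deadline=None
)
hypothesis.settings.load_profile("suite")


# Published predicted m/z ladder for free RNase A (rows z=1..10, X=0..5).
PRINTED_LADDER_FREE = {
    1: [13682.3, 13780.3, 13878.3, 13976.3, 14074.3, 14172.3],
    2: [6841.7, 6890.7, 6939.7, 6988.7, 7037.7, 7086.7],
    3: [4561.4, 4594.1, 4626.8, 4659.4, 4692.1, 4724.8],
    4: [3421.3, 3445.8, 3470.3, 3494.8, 3519.3, 3543.8],
    5: [2737.3, 2756.9, 2776.5, 2796.1, 2815.7, 2835.3],
    6: [2281.2, 2297.6, 2313.9, 2330.2, 2346.6, 2362.9],
    7: [1955.5, 1969.5, 1983.5, 1997.5, 2011.5, 2025.5],
    8: [1711.2, 1723.4, 1735.7, 1747.9, 1760.2, 1772.4],
    9: [1521.2, 1532.0, 1542.9, 1553.8, 1564.7, 1575.6],
    10: [1369.1, 1378.9, 1388.7, 1398.5, 1408.3, 1418.1],
}

# Published ladders for the two ligand-bound forms.
PRINTED_LADDER_DC5 = {
    1: [15066.2, 15164.2, 15262.2, 15360.2, 15458.2, 15556.2],
    2: [7533.6, 7582.6, 7631.6, 7680.6, 7729.6, 7778.6],
    3: [5022.7, 5055.4, 5088.1, 5120.7, 5153.4, 5186.1],
    4: [3767.3, 3791.8, 3816.3, 3840.8, 3865.3, 3889.8],
    5: [3014.1, 3033.7, 3053.3, 3072.9, 3092.5, 3112.1],
    6: [2511.9, 2528.2, 2544.5, 2560.9, 2577.2, 2593.5],
    7: [2153.2, 2167.2, 2181.2, 2195.2, 2209.2, 2223.2],
    8: [1884.2, 1896.4, 1908.7, 1920.9, 1933.2, 1945.4],
    9: [1674.9, 1685.8, 1696.7, 1707.6, 1718.5, 1729.4],
    10: [1507.5, 1517.3, 1527.1, 1536.9, 1546.7, 1556.5],
}
PRINTED_LADDER_DC2AC2 = {
    1: [15090.3, 15188.3, 15286.3, 15384.3, 15482.3, 15580.3],
    2: [7545.7, 7594.7, 7643.7, 7692.7, 7741.7, 7790.7],
    3: [5030.8, 5063.4, 5096.1, 5128.8, 5161.4, 5194.1],
    4: [3773.3, 3797.8, 3822.3, 3846.8, 3871.3, 3895.8],
    5: [3018.9, 3038.5, 3058.1, 3077.7, 3097.3, 3116.9],
    6: [2515.9, 2532.2, 2548.6, 2564.9, 2581.2, 2597.6],
    7: [2156.6, 2170.6, 2184.6, 2198.6, 2212.6, 2226.6],
    8: [1887.2, 1899.4, 1911.7, 1923.9, 1936.2, 1948.4],
    9: [1677.6, 1688.5, 1699.4, 1710.3, 1721.2, 1732.0],
    10: [1509.9, 1519.7, 1529.5, 1539.3, 1549.1, 1558.9],
}

# Published +8 integration windows (X = 0..5, 0.5 Th pad).
PRINTED_WINDOWS = {
    "free": (1710.7, 1772.9),
    "dC5": (1883.7, 1945.9),
    "dC2AC2": (1886.7, 1948.9),
}

# Blank (no-ligand) free-protein abundances and their published statistics.
BLANK_ABUNDANCES = [71438882, 80188529, 70622004, 94929471, 61169836, 65198871]
BLANK_STATS = {"mean": 73924599, "sd": 12135483, "rsd_pct": 16.4}


@pytest.fixture
def free_protein() -> SpeciesDefinition:
    return SpeciesDefinition("free", RNASE_A_MASS, max_adducts=8)


@pytest.fixture
def dc5_bound(free_protein) -> SpeciesDefinition:
    return free_protein.with_ligand("bound", DC5_MASS)


@pytest.fixture
def dc2ac2_bound(free_protein) -> SpeciesDefinition:
    return free_protein.with_ligand("bound", DC2AC2_MASS)
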