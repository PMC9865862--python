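import pytest

from porphyrintools import SimulationConfig, simulate_peaklist
from porphyrintools.synthetic_data import fixture_config


@pytest.fixture(scope="session")
def fixture_run():
    """A seeded synthetic LC-MS run planting all four porphyrin/hemin pairs."""
    cfg = fixture_config(seed=42, ppm_sigma=1.0, n_decoys=50)
    peaks, manifest = simulate_peaklist(cfg)
    return cfg, peaks, manifest


# reference HRMS "calcd" m/z values for the four porphyrin/hemin pairs
# (free base, ferric ion, ACN adduct each): (cation composition, calcd m/z)
CALCD_VALUES = [
    ("C24H23N4", 367.1923),
    ("C24H20N4Fe", 420.1037),
    ("C26H23N5Fe", 461.1303),
    ("C27H27N4O2", 439.2134),
    ("C27H24N4O2Fe", 492.1249),
    ("C29H27N5O2Fe", 533.1514),
    ("C32H35N4O4", 539.2658),
    ("C32H32N4O4Fe", 592.1773),
    ("C34H35N5O4Fe", 633.2038),
    ("C30H31N4O4", 511.2345),
    ("C30H28N4O4Fe", 564.1460),
    ("C32H31N5O4Fe", 605.1725),
]
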