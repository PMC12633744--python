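import numpy as np
import pytest

from syrinx_resonance import load_reference_specimens

#: Published resonance predictions (Hz) for the µCT reference collection,
#: keyed by (catalog_id, side) — the oracle the geometry model must
#: reproduce from the printed V / d / L columns.
PUBLISHED_RESONANCES_HZ = {
    ("MCZ:Orn:341876", "left"): 3405.92,
    ("MCZ:Orn:347504", "left"): 3111.78,
    ("MCZ:Orn:342070", "left"): 2157.74,
    ("MCZ:Orn:347156", "left"): 2757.61,
    ("MCZ:Orn:335525", "left"): 2337.92,
    ("MCZ:Orn:346547", "left"): 2459.33,
    ("MCZ:Orn:346918", "left"): 2691.36,
    ("MCZ:Orn:341918", "left"): 3079.34,
    ("MCZ:Orn:340385", "left"): 3290.00,
    ("MCZ:Orn:347155", "left"): 1030.91,
    ("MCZ:Orn:347155", "right"): 3179.06,
    ("MCZ:Orn:343209", "left"): 1479.81,
    ("MCZ:Orn:340273", "left"): 2392.71,
    ("MCZ:Orn:366269", "left"): 1647.77,
    ("MCZ:Orn:336960", "left"): 1506.11,
    ("MCZ:Orn:342699", "left"): 3230.34,
    ("MCZ:Orn:340383", "left"): 2242.77,
    ("MCZ:Orn:341891", "left"): 1568.31,
    ("MCZ:Orn:341891", "right"): 1725.71,
    ("MCZ:Orn:341905", "left"): 1656.23,
    ("MCZ:Orn:341905", "right"): 1946.70,
    ("MCZ:Orn:342835", "left"): 1621.77,
    ("MCZ:Orn:342835", "right"): 1994.08,
    ("MCZ:Orn:336858", "left"): 3197.39,
    ("MCZ:Orn:337334", "left"): 3417.18,
    ("MCZ:Orn:342589", "left"): 3377.43,
    ("MCZ:Orn:342590", "left"): 3676.69,
    ("MCZ:Orn:342591", "left"): 3695.10,
    ("MCZ:Orn:342206", "left"): 2476.04,
    ("MCZ:Orn:347540", "left"): 2360.11,
    ("MCZ:Orn:347540", "right"): 3433.64,
}


@pytest.fixture(scope="session")
def reference_specimens():
    return load_reference_specimens()


@pytest.fixture(scope="session")
def published_resonances():
    return PUBLISHED_RESONANCES_HZ


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
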