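import numpy as np
import pytest

from mammodose import datasets, synthetic
from mammodose.curves import Quantity
from mammodose.dosimetry import FactorTables
from mammodose.model import ScreeningDoseResults


@pytest.fixture(scope="session")
def published():
    """Pre-trained model components from the packaged coefficients."""
    return ScreeningDoseResults.from_published()


@pytest.fixture(scope="session")
def mbd_family(published):
    return published.mbd_family


@pytest.fixture(scope="session")
def cbt_family(published):
    return published.cbt_family


@pytest.fixture(scope="session")
def mas_family(published):
    return published.mas_family


@pytest.fixture(scope="session")
def lookup(published):
    return published.kvp_tf_lookup


@pytest.fixture(scope="session")
def lar_model():
    return datasets.load_lar_model()


@pytest.fixture(scope="session")
def category_table():
    return datasets.load_category_median_mgd()


@pytest.fixture(scope="session")
def qa():
    return synthetic.default_qa_parameters()


@pytest.fixture(scope="session")
def factor_tables():
    return synthetic.generate_factor_tables(seed=0)


@pytest.fixture(scope="session")
def unit_factor_tables():
    """Grids that are 1.0 everywhere: interpolation becomes the identity."""
    hvl = (0.2, 0.5, 0.8)
    cbt = (20.0, 60.0, 110.0)
    gland = (0.0, 50.0, 100.0)
    return FactorTables(
        g_hvl=hvl, g_cbt=cbt, g_values=np.ones((3, 3)),
        c_hvl=hvl, c_cbt=cbt, c_gland=gland, c_values=np.ones((3, 3, 3)),
        s_values={"W/Rh": 1.0, "W/Ag": 1.0},
    )


@pytest.fixture(scope="session")
def client_a():
    """The worked first-visit example: age 56, 26.68% MBD, 40.75 mm CBT,
    28 kVp, 88.8 mAs, W/Rh."""
    return dict(age=56, mbd_pct=26.68, cbt_mm=40.75, kvp=28, mas=88.8, target_filter="W/Rh")
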