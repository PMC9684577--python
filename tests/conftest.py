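import numpy as np
import pytest

from iopcorr.cohort import Cohort, EyeRecord
from iopcorr.synthetic import default_params, generate


@pytest.fixture
def record():
    return EyeRecord("S1", age=42.0, cct_um=545.0, iop_gat=15.0,
                     iop_dct=17.0, r_mm=7.8)


@pytest.fixture
def small_cohort():
    recs = [
        EyeRecord("S1", age=30.0, cct_um=520.0, iop_gat=14.0, iop_dct=16.5, r_mm=7.6),
        EyeRecord("S2", age=45.0, cct_um=545.0, iop_gat=15.5, iop_dct=17.0, r_mm=7.8),
        EyeRecord("S3", age=60.0, cct_um=580.0, iop_gat=17.0, iop_dct=18.5, r_mm=8.0),
    ]
    return Cohort(records=recs, label="tiny")


@pytest.fixture(scope="session")
def default_cohort_1k():
    """A moderately sized generated cohort shared across tests."""
    return generate(default_params(n=1000, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
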