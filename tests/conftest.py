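import numpy as np
import pytest

from ctgscreen.records import FHRRecord
from ctgscreen.synthetic import CohortSpec, simulate_record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_record():
    n = 4800
    return FHRRecord(
        subject_id="const",
        fhr=np.full(n, 140.0),
        quality=np.full(n, 2, dtype=np.int8),
        ga_weeks=38.0,
        fetal_sex="female",
        maternal_age=30.0,
        group="healthy",
    )


@pytest.fixture
def healthy_record():
    spec = CohortSpec()
    return simulate_record(spec, "healthy", "H000", np.random.default_rng(7))


@pytest.fixture
def iugr_record():
    spec = CohortSpec()
    return simulate_record(spec, "iugr", "I000", np.random.default_rng(8))
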