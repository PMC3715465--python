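import io

import numpy as np
import pandas as pd
import pytest

from mirqpcr.qpcr_io import CtMatrix
from mirqpcr.synthetic_data import (
    ArrayPhaseConfig,
    calibrate_to_paper_defaults,
    generate_array_phase,
    generate_validation_cohort,
)


@pytest.fixture
def small_ct() -> CtMatrix:
    """3 samples x 2 assays with one undetermined cell."""
    ct = pd.DataFrame(
        {"miR-a": [20.0, 22.0, 24.0], "miR-b": [25.0, np.nan, 27.0]},
        index=["S1", "S2", "S3"],
    )
    return CtMatrix(ct, ~ct.isna())


@pytest.fixture
def wide_csv() -> io.StringIO:
    return io.StringIO(
        "sample_id,miR-a,miR-b\nS1,20.0,25.0\nS2,22.0,Undetermined\nS3,24.0,27.0\n"
    )


@pytest.fixture(scope="session")
def validation_cohort():
    return generate_validation_cohort(calibrate_to_paper_defaults(seed=0))


@pytest.fixture(scope="session")
def array_cohort():
    return generate_array_phase(ArrayPhaseConfig(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
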