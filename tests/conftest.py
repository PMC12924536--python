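import numpy as np
import pandas as pd
import pytest

from strataprot.data_io import AbundanceMatrix, SampleMetadata
from strataprot.synthetic_data import desk_shape, generate_cohort


@pytest.fixture
def tiny_matrix():
    """3 proteins x 4 samples, raw scale, one missing cell."""
    vals = pd.DataFrame(
        [[100.0, 200.0, 150.0, 120.0],
         [50.0, np.nan, 60.0, 55.0],
         [1024.0, 1.0, 2.0, 4.0]],
        index=pd.Index(["P1", "P2", "P3"], name="protein_id"),
        columns=["S1", "S2", "S3", "S4"])
    return AbundanceMatrix(vals, scale="raw")


@pytest.fixture
def tiny_metadata():
    df = pd.DataFrame({
        "histotype": ["HGSC", "HGSC", "MC", "MC"],
        "stage": ["I", "III", "II", "IV"],
        "age": [55.0, 63.0, 47.0, 71.0],
        "os_time": [1000.0, 400.0, 2000.0, 150.0],
        "os_event": [0, 1, 0, 1],
        "dss_time": [1000.0, 400.0, 2000.0, 150.0],
        "dss_event": [0, 1, 0, 0],
    }, index=pd.Index(["S1", "S2", "S3", "S4"], name="sample_id"))
    return SampleMetadata(df)


@pytest.fixture(scope="session")
def desk_cohort():
    """A clean desk-shape cohort (no planted effects, no missingness)."""
    cfg = desk_shape(n_proteins=60, seed=101, detection_quantile=0.0)
    return generate_cohort(cfg)
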