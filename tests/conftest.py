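import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from metsig.datamodel import ExpressionMatrix, SignatureDefinition

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples of raw counts."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[10, 20, 30, 40], [5, 5, 5, 5], [1, 2, 3, 4]],
            index=["CDC42", "FLAT", "G1"],
            columns=["S1", "S2", "S3", "S4"],
        ),
        unit="raw_counts",
    )


@pytest.fixture
def two_gene_signature():
    return SignatureDefinition("CDC42", ["SIG1", "SIG2"])
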