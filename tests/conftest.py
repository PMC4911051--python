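import numpy as np
import pandas as pd
import pytest

from tnbctype.io_formats import ExpressionMatrix
from tnbctype.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 2 samples with hand-picked values."""
    df = pd.DataFrame(
        [[1.5, 2.5], [3.0, 4.0], [5.25, 6.75]],
        index=["G1", "G2", "G3"], columns=["S1", "S2"])
    return ExpressionMatrix(df)


@pytest.fixture(scope="session")
def default_cohort() -> dict:
    """The default synthetic cohort (n=500, seed 11), shared read-only."""
    return generate_cohort(CohortConfig(n_samples=500, seed=11))


@pytest.fixture(scope="session")
def subtyped_default_cohort(default_cohort) -> list:
    """Subtype results for every sample of the default cohort."""
    from tnbctype.centroid_subtyping import subtype_samples
    return subtype_samples(default_cohort["expression"],
                           default_cohort["centroids"])
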