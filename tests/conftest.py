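import numpy as np
import pytest

from reopure import ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 2 samples, linear scale."""
    return ExpressionMatrix(
        ["gA", "gB", "gC"],
        ["s1", "s2"],
        np.array([[1.0, 2.0], [3.5, 0.5], [2.25, 7.0]]),
        "linear",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170227)
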