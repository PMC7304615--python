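import numpy as np
import pytest

from fsint.linmod import SampleData


@pytest.fixture
def toy_data():
    """Four samples, intercept-only design, half-and-half genotype."""
    return SampleData(
        trait=np.array([1.0, 2.0, 3.0, 4.0]),
        covariates=np.ones((4, 1)),
        genotype=np.array([0.0, 0.0, 1.0, 1.0]),
    )


@pytest.fixture
def covariate_data():
    """A realistic small dataset: two covariates, common variant, null effect."""
    rng = np.random.default_rng(1234)
    n = 400
    x1 = rng.normal(size=n)
    x2 = rng.integers(0, 2, n).astype(float)
    g = rng.binomial(2, 0.3, size=n).astype(float)
    y = 0.5 * x1 + 0.5 * x2 + rng.normal(size=n)
    return SampleData(
        trait=y,
        covariates=np.column_stack([np.ones(n), x1, x2]),
        genotype=g,
    )
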