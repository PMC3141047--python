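import numpy as np
import pytest

from gsppr import DescriptorTable


def make_table(
    n: int = 50,
    p: int = 5,
    seed: int = 0,
    coefficients=None,
    noise_sd: float = 0.0,
    response=None,
) -> DescriptorTable:
    """Small random descriptor table with an optional planted linear signal."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    if response is not None:
        y = response(X, rng)
    elif coefficients is not None:
        y = X[:, : len(coefficients)] @ np.asarray(coefficients, dtype=float)
        y = y + noise_sd * rng.standard_normal(n)
    else:
        y = rng.standard_normal(n)
    return DescriptorTable(
        compound_ids=[f"c{i:03d}" for i in range(n)],
        descriptor_names=[f"d{j:02d}" for j in range(p)],
        values=X,
        activity=y,
    )


@pytest.fixture
def small_table() -> DescriptorTable:
    return make_table(n=30, p=4, seed=7, coefficients=[2.0, -1.0], noise_sd=0.1)
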