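import numpy as np
import pytest

from dcss import ExpressionMatrix, toy_matrix


@pytest.fixture
def toy():
    """The 2 x 3 worked example with one collinear column pair."""
    return toy_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_count_matrix(rng, n, d, lam=5.0):
    """A dense random non-negative count matrix (Poisson entries),
    re-drawn until numerically full rank so any k <= min(n, d) is valid."""
    for _ in range(10):
        vals = rng.poisson(lam, size=(n, d)).astype(float)
        s = np.linalg.svd(vals, compute_uv=False)
        if s[-1] > 1e-8 * s[0]:
            return ExpressionMatrix(vals)
    raise RuntimeError("failed to draw a full-rank count matrix")
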