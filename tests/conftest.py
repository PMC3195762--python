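import numpy as np
import pytest

from gndpca.tensor import tucker_reconstruct


def random_orthonormal(rng, n, k):
    q, _ = np.linalg.qr(rng.standard_normal((n, k)))
    return q


def max_principal_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Largest principal angle between the column spaces of a and b, via the
    sine formulation (accurate for angles near 0, unlike arccos of singular
    values of a'b)."""
    qa, _ = np.linalg.qr(a)
    qb, _ = np.linalg.qr(b)
    resid = qb - qa @ (qa.T @ qb)
    s = np.linalg.svd(resid, compute_uv=False)
    return float(np.arcsin(np.clip(s.max(), 0.0, 1.0)))


def lowrank_cohort(rng, shape=(32, 32, 16), ranks=(8, 8, 4), m=20):
    """Cohort generated exactly as B_i x_n U_n from fixed orthonormal
    factors; returns (samples, true factors)."""
    factors = [random_orthonormal(rng, s, r) for s, r in zip(shape, ranks)]
    samples = [
        tucker_reconstruct(rng.standard_normal(ranks), factors) for _ in range(m)
    ]
    return samples, factors


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
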