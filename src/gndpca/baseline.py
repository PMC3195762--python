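"""Vectorized-PCA ("eigenface") baseline.

Classical PCA on flattened volumes: each sample becomes a voxel-length
vector, and the model keeps the leading eigenvectors of the sample
covariance.  With M training samples the centered data have rank at most
M - 1, so the basis is computed with the M x M Gram-matrix trick — the full
voxel-by-voxel covariance is never formed.  This is the comparison method
that overfits when M is far below the voxel count, which the multilinear
model is designed to avoid.

Flattening uses the mode-1 unfolding convention of :mod:`gndpca.tensor`
(first mode fastest) so cores and eigen-coefficients live in a consistent
layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EigenfaceModel", "fit_eigenface", "reconstruct_eigenface"]


@dataclass
class EigenfaceModel:
    """PCA of flattened volumes.

    mean : flattened mean intensity vector, length D
    basis : (D, K) orthonormal eigen-volumes, K <= M - 1
    eigenvalues : descending, length K
    shape : original tensor shape, for reshaping reconstructions
    """

    mean: np.ndarray
    basis: np.ndarray
    eigenvalues: np.ndarray
    shape: tuple[int, ...]

    @property
    def n_components(self) -> int:
        return self.basis.shape[1]


def _flatten(t: np.ndarray) -> np.ndarray:
    return np.asarray(t, dtype=float).ravel(order="F")


def fit_eigenface(samples) -> EigenfaceModel:
    """PCA of flattened centered samples via the Gram-matrix trick.

    Eigenpairs of the M x M Gram matrix ``X X' / M`` give the nonzero
    spectrum of the covariance ``X' X / M``; components with eigenvalue below
    1e-12 of the largest are dropped.
    """
    arr = [np.asarray(s, dtype=float) for s in samples]
    if len(arr) < 2:
        raise ValueError("eigenface PCA needs at least 2 samples")
    shape = arr[0].shape
    if any(a.shape != shape for a in arr):
        raise ValueError("all samples must share one shape")
    x = np.stack([_flatten(a) for a in arr])  # (M, D)
    mean = x.mean(axis=0)
    xc = x - mean
    m = xc.shape[0]
    gram = xc @ xc.T / m
    w, v = np.linalg.eigh(gram)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    keep = w > 1e-12 * max(w[0], 1e-300)
    w, v = w[keep], v[:, keep]
    # lift Gram eigenvectors to voxel space and normalize
    basis = xc.T @ v / np.sqrt(m * w)[None, :]
    # deterministic signs: largest-magnitude entry positive
    idx = np.argmax(np.abs(basis), axis=0)
    signs = np.sign(basis[idx, np.arange(basis.shape[1])])
    signs[signs == 0] = 1.0
    basis *= signs
    return EigenfaceModel(mean=mean, basis=basis, eigenvalues=w, shape=shape)


def reconstruct_eigenface(model: EigenfaceModel, t: np.ndarray, k: int | None = None) -> np.ndarray:
    """Project ``t`` onto the top-k eigen-volumes and reconstruct.

    ``k=None`` uses all components; ``k=0`` returns the mean.
    """
    t = np.asarray(t, dtype=float)
    if t.shape != model.shape:
        raise ValueError(f"expected shape {model.shape}, got {t.shape}")
    if k is None:
        k = model.n_components
    if not (0 <= k <= model.n_components):
        raise ValueError(f"k must be in 0..{model.n_components}, got {k}")
    d = _flatten(t) - model.mean
    b = model.basis[:, :k]
    rec = model.mean + b @ (b.T @ d)
    return rec.reshape(model.shape, order="F")
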