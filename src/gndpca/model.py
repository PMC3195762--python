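"""Generalized N-dimensional PCA (GND-PCA).

GND-PCA fits one orthonormal factor matrix per tensor mode to a cohort of
same-shape tensors, minimizing the total Tucker reconstruction error

    C = sum_i || A_i - B_i x_1 U1 x_2 U2 ... x_N UN ||_F^2

over zero-mean samples, where the core ``B_i = A_i x_1 U1' ... x_N UN'`` is
the sample's low-dimensional feature.  Unlike vectorized ("eigenface") PCA,
the basis is a tensor product of small per-mode subspaces, which keeps the
parameter count low and generalizes from very few training samples.

The minimization alternates over modes (higher-order orthogonal iteration
generalized to a sample set): with all other factors fixed, the optimal
``Un`` consists of the leading eigenvectors of the aggregate scatter of the
partially projected samples, so the cost is non-increasing across sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh

from .tensor import frobenius_norm, mode_product, tucker_reconstruct, unfold

__all__ = [
    "FitConfig",
    "GNDPCAModel",
    "center",
    "init_factors",
    "fit",
    "project",
    "reconstruct",
    "cost",
    "normalized_correlation",
    "save_model",
    "load_model",
]


@dataclass
class FitConfig:
    """Controls for the alternating fit.

    Parameters
    ----------
    ranks : tuple of int
        Target per-mode subspace dimensions (J1, ..., JN), each Jn <= In.
    max_iter : int
        Maximum number of full sweeps over the modes.
    tol : float
        Stop when the relative cost change between sweeps falls below this.
    init : str
        ``"hosvd"`` (deterministic per-mode PCA of concatenated unfoldings)
        or ``"random"`` (seeded random orthonormal start).
    seed : int
        Only used for ``init="random"``.
    """

    ranks: tuple[int, ...]
    max_iter: int = 50
    tol: float = 1e-6
    init: str = "hosvd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.init not in ("hosvd", "random"):
            raise ValueError(f"init must be 'hosvd' or 'random', got {self.init!r}")


@dataclass
class GNDPCAModel:
    """Fitted multilinear texture model.

    Attributes
    ----------
    mean : ndarray
        Entrywise training mean; subtracted before projection.
    factors : list of ndarray
        Per-mode orthonormal bases, factors[n] of shape (In, Jn).
    ranks : tuple of int
    fit_history : list of float
        Total squared reconstruction cost after each full sweep
        (non-increasing).
    converged : bool
    n_train : int
    """

    mean: np.ndarray
    factors: list[np.ndarray]
    ranks: tuple[int, ...]
    fit_history: list[float] = field(default_factory=list)
    converged: bool = False
    n_train: int = 0


def _as_stack(samples) -> np.ndarray:
    """Stack a sequence of same-shape tensors into an (M, ...) float array."""
    arr = np.stack([np.asarray(s, dtype=float) for s in samples])
    if arr.shape[0] < 1:
        raise ValueError("need at least one sample")
    if not np.all(np.isfinite(arr)):
        raise ValueError("samples contain non-finite values")
    return arr


def center(samples) -> tuple[np.ndarray, np.ndarray]:
    """Return (mean, centered) for a set of same-shape tensors."""
    arr = _as_stack(samples)
    mean = arr.mean(axis=0)
    return mean, arr - mean


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Fix each column's sign so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def _top_eigvecs(scatter: np.ndarray, k: int) -> np.ndarray:
    """Leading-k eigenvectors of a symmetric PSD matrix, deterministically
    ordered (descending eigenvalue, index order on ties) and sign-fixed."""
    n = scatter.shape[0]
    w, v = eigh(scatter, subset_by_index=(n - k, n - 1))
    # eigh returns ascending order
    v = v[:, ::-1]
    return _fix_signs(v)


def init_factors(centered, ranks: tuple[int, ...]) -> list[np.ndarray]:
    """HOSVD-style start: per mode, the leading left singular vectors of the
    concatenated mode-n unfoldings of all (centered) samples."""
    arr = _as_stack(centered)
    shape = arr.shape[1:]
    _check_ranks(ranks, shape)
    factors = []
    for n in range(len(shape)):
        scatter = np.zeros((shape[n], shape[n]))
        for a in arr:
            un = unfold(a, n + 1)
            scatter += un @ un.T
        factors.append(_top_eigvecs(scatter, ranks[n]))
    return factors


def _check_ranks(ranks, shape) -> tuple[int, ...]:
    ranks = tuple(int(r) for r in ranks)
    if len(ranks) != len(shape):
        raise ValueError(f"need {len(shape)} ranks, got {len(ranks)}")
    for r, s in zip(ranks, shape):
        if not (1 <= r <= s):
            raise ValueError(f"ranks {ranks} invalid for tensor shape {tuple(shape)}")
    return ranks


def _random_orthonormal(shape, ranks, seed) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    out = []
    for s, r in zip(shape, ranks):
        q, _ = np.linalg.qr(rng.standard_normal((s, r)))
        out.append(_fix_signs(q))
    return out


def _project_except(t: np.ndarray, factors, skip: int) -> np.ndarray:
    """Apply Un' on every mode except ``skip`` (0-based)."""
    out = t
    for m, u in enumerate(factors):
        if m != skip:
            out = mode_product(out, u.T, m + 1)
    return out


def fit(samples, config: FitConfig) -> GNDPCAModel:
    """Fit per-mode orthonormal bases by alternating eigen-updates.

    Each mode update sets Un to the leading eigenvectors of the aggregate
    scatter ``S_n = sum_i Y_i(n) Y_i(n)'`` where ``Y_i`` is sample i projected
    on all other modes' current factors; this is the exact minimizer of the
    cost with the other factors held fixed, computed from the projected
    unfoldings (shape In x prod Jm) so no Kronecker product is materialized.
    """
    mean, centered = center(samples)
    shape = centered.shape[1:]
    ndim = len(shape)
    ranks = _check_ranks(config.ranks, shape)

    if config.init == "random":
        factors = _random_orthonormal(shape, ranks, config.seed)
    else:
        factors = init_factors(centered, ranks)

    total_energy = float(np.sum(centered**2))
    history: list[float] = []
    converged = False
    for _ in range(config.max_iter):
        for n in range(ndim):
            scatter = np.zeros((shape[n], shape[n]))
            for a in centered:
                y = unfold(_project_except(a, factors, n), n + 1)
                scatter += y @ y.T
            factors[n] = _top_eigvecs(scatter, ranks[n])
        # cost after a full sweep; for orthonormal factors
        # C = sum ||A_i||^2 - sum ||B_i||^2
        core_energy = 0.0
        for a in centered:
            b = _project_except(a, factors, skip=-1)
            core_energy += float(np.sum(b**2))
        c = max(total_energy - core_energy, 0.0)
        history.append(c)
        if len(history) >= 2:
            prev = history[-2]
            denom = prev if prev > 0 else 1.0
            if abs(prev - c) / denom < config.tol:
                converged = True
                break
        elif c <= config.tol * max(total_energy, 1.0):
            converged = True
            break

    return GNDPCAModel(
        mean=mean,
        factors=factors,
        ranks=ranks,
        fit_history=history,
        converged=converged,
        n_train=centered.shape[0],
    )


def project(model: GNDPCAModel, t: np.ndarray) -> np.ndarray:
    """Core-tensor feature of ``t``: subtract the training mean, then apply
    Un' along every mode.  Output shape equals the model ranks."""
    t = np.asarray(t, dtype=float)
    if t.shape != model.mean.shape:
        raise ValueError(f"expected shape {model.mean.shape}, got {t.shape}")
    out = t - model.mean
    for n, u in enumerate(model.factors):
        out = mode_product(out, u.T, n + 1)
    return out


def reconstruct(model: GNDPCAModel, core: np.ndarray) -> np.ndarray:
    """Tucker reconstruction of a core feature plus the training mean."""
    core = np.asarray(core, dtype=float)
    if core.shape != tuple(model.ranks):
        raise ValueError(f"expected core shape {tuple(model.ranks)}, got {core.shape}")
    return tucker_reconstruct(core, model.factors) + model.mean


def cost(model: GNDPCAModel, samples) -> float:
    """Total squared reconstruction error of ``samples`` under the model."""
    arr = _as_stack(samples)
    if arr.shape[1:] != model.mean.shape:
        raise ValueError(f"expected shape {model.mean.shape}, got {arr.shape[1:]}")
    total = 0.0
    for a in arr:
        rec = reconstruct(model, project(model, a))
        total += frobenius_norm(a - rec) ** 2
    return total


def normalized_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of the flattened intensities, in [-1, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("inputs must have the same shape")
    da = a - a.mean()
    db = b - b.mean()
    na = np.linalg.norm(da)
    nb = np.linalg.norm(db)
    if na == 0 or nb == 0:
        raise ValueError("normalized correlation undefined for zero-variance input")
    return float(np.clip(da @ db / (na * nb), -1.0, 1.0))


def save_model(model: GNDPCAModel, path) -> None:
    """Serialize a model to a single ``.npz`` archive.

    Layout: ``mean`` (array), ``factor_0..factor_{N-1}`` (arrays), ``ranks``,
    ``fit_history``, ``converged`` (0/1), ``n_train``.
    """
    payload = {
        "mean": model.mean,
        "ranks": np.asarray(model.ranks, dtype=np.int64),
        "fit_history": np.asarray(model.fit_history, dtype=float),
        "converged": np.asarray(int(model.converged)),
        "n_train": np.asarray(int(model.n_train)),
    }
    for n, u in enumerate(model.factors):
        payload[f"factor_{n}"] = u
    np.savez(path, **payload)


def load_model(path) -> GNDPCAModel:
    """Load a model saved by :func:`save_model`."""
    with np.load(path) as z:
        ranks = tuple(int(r) for r in z["ranks"])
        factors = [z[f"factor_{n}"] for n in range(len(ranks))]
        return GNDPCAModel(
            mean=z["mean"],
            factors=factors,
            ranks=ranks,
            fit_history=[float(c) for c in z["fit_history"]],
            converged=bool(int(z["converged"])),
            n_train=int(z["n_train"]),
        )
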