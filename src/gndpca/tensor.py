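"""Order-N tensor algebra: unfolding, mode products, Tucker reconstruction.

These primitives implement the multilinear (Tucker) model

    A* = B x_1 U1 x_2 U2 ... x_N UN

where ``B`` is a small core tensor and each ``Un`` is a factor matrix acting
along mode ``n``.  The public use case is order 3 (volumetric images), but
everything here is generic over the tensor order.

Unfolding convention
--------------------
``unfold(t, mode)`` puts mode ``n`` on the rows; the columns enumerate the
remaining modes in increasing mode order with the *first* listed mode varying
fastest.  For an I1 x I2 x I3 tensor, ``unfold(t, 1)[i1, :]`` walks i2 fastest,
then i3.  ``fold`` is its exact inverse.  Any self-consistent convention gives
identical costs and reconstructions; this one is fixed so serialized models
and flattened features are portable.

Modes are 1-based in the public API, matching the standard x_n notation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "unfold",
    "fold",
    "mode_product",
    "tucker_reconstruct",
    "frobenius_norm",
]


def _check_mode(mode: int, ndim: int) -> int:
    if not (1 <= mode <= ndim):
        raise ValueError(f"mode must be in 1..{ndim}, got {mode}")
    return mode - 1


def unfold(t: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n matricization of ``t``.

    Rows index mode ``n``; columns iterate the remaining modes in increasing
    mode order, the first of them varying fastest (Fortran order over the
    remaining axes).

    Parameters
    ----------
    t : ndarray
        Input tensor of any order >= 1.
    mode : int
        1-based mode index.

    Returns
    -------
    ndarray of shape ``(t.shape[mode-1], prod(other dims))``
    """
    t = np.asarray(t)
    ax = _check_mode(mode, t.ndim)
    moved = np.moveaxis(t, ax, 0)
    # remaining axes stay in increasing order; Fortran ravel makes the first
    # remaining mode vary fastest
    return moved.reshape(t.shape[ax], -1, order="F")


def fold(m: np.ndarray, mode: int, shape: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`unfold` under the same convention.

    Parameters
    ----------
    m : ndarray
        Matrix of shape ``(shape[mode-1], prod(remaining dims))``.
    mode : int
        1-based mode index.
    shape : tuple of int
        Shape of the tensor to reconstruct.
    """
    m = np.asarray(m)
    shape = tuple(int(s) for s in shape)
    ax = _check_mode(mode, len(shape))
    rest = shape[:ax] + shape[ax + 1 :]
    expected = (shape[ax], int(np.prod(rest)) if rest else 1)
    if m.shape != expected:
        raise ValueError(
            f"fold: expected matrix of shape {expected} for mode {mode} and "
            f"tensor shape {shape}, got {m.shape}"
        )
    moved = m.reshape((shape[ax],) + rest, order="F")
    return np.moveaxis(moved, 0, ax)


def mode_product(t: np.ndarray, u: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n product ``t x_n u``.

    Satisfies ``unfold(result, mode) == u @ unfold(t, mode)``; the output
    shape replaces the mode-n extent by ``u.shape[0]``.
    """
    t = np.asarray(t)
    u = np.asarray(u)
    ax = _check_mode(mode, t.ndim)
    if u.ndim != 2 or u.shape[1] != t.shape[ax]:
        raise ValueError(
            f"mode_product: matrix of shape {u.shape} cannot act on mode "
            f"{mode} of a tensor with shape {t.shape}"
        )
    return np.moveaxis(np.tensordot(u, t, axes=(1, ax)), 0, ax)


def tucker_reconstruct(core: np.ndarray, factors: list[np.ndarray]) -> np.ndarray:
    """Reconstruct ``core x_1 U1 x_2 ... x_N UN``.

    ``factors[n-1]`` acts along mode ``n`` and must have as many columns as
    the core's extent in that mode.
    """
    core = np.asarray(core)
    if len(factors) != core.ndim:
        raise ValueError(
            f"need {core.ndim} factor matrices for an order-{core.ndim} core, "
            f"got {len(factors)}"
        )
    out = core
    for n, u in enumerate(factors, start=1):
        out = mode_product(out, u, n)
    return out


def frobenius_norm(t: np.ndarray) -> float:
    """Frobenius norm: the 2-norm of the flattened tensor."""
    return float(np.linalg.norm(np.asarray(t).ravel()))
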