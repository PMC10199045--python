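"""Kronecker-product algebra and factored linear maps on gradient matrices.

A learned preconditioner for a gradient matrix ``G ∈ R^{m×n}`` is stored as a
pair of small square factors ``(L ∈ R^{m×m}, R ∈ R^{n×n})`` and applied as
``L @ G @ R``.  Under column-major (Fortran) vectorisation this is the action
of the large structured matrix ``Rᵀ ⊗ L``::

    vec(L G R) = (Rᵀ ⊗ L) vec(G)

so the pair represents an ``mn × mn`` linear map with only ``m² + n²``
parameters, and the identity map lies in its span (``L = I_m, R = I_n``).
:func:`kron` materialises the full product and exists for documentation and
as a test oracle only; the training hot path always uses :func:`apply_factored`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, matmul, transpose

__all__ = ["FactorPair", "kron", "apply_factored", "identity_factors"]


@dataclass
class FactorPair:
    """Left/right Kronecker factors preconditioning one gradient matrix.

    ``left`` is ``m×m``, ``right`` is ``n×n``, and ``shape_tag = (m, n)`` names
    the 2-D shape of the gradient matrix the pair acts on.
    """

    left: Tensor
    right: Tensor
    shape_tag: tuple[int, int]

    def __post_init__(self):
        m, n = self.shape_tag
        if self.left.data.shape != (m, m):
            raise ValueError(
                f"left factor must be {m}x{m}, got {self.left.data.shape}"
            )
        if self.right.data.shape != (n, n):
            raise ValueError(
                f"right factor must be {n}x{n}, got {self.right.data.shape}"
            )
        if not (np.isfinite(self.left.data).all() and np.isfinite(self.right.data).all()):
            raise ValueError("factors must be all-finite")


def kron(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Kronecker product of two matrices (test oracle; never the hot path).

    Block ``(i, j)`` of the result equals ``A[i, j] * B``.
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.size == 0 or B.size == 0:
        raise ValueError("kron requires non-empty matrices")
    if A.ndim != 2 or B.ndim != 2:
        raise ValueError("kron requires 2-D matrices")
    if not (np.isfinite(A).all() and np.isfinite(B).all()):
        raise ValueError("kron requires all-finite matrices")
    return np.kron(A, B)


def apply_factored(G: Tensor | np.ndarray, F: FactorPair) -> Tensor:
    """Apply the factored map ``G ↦ L G R`` (≙ ``(Rᵀ⊗L) vec(G)``).

    Differentiable in ``G`` and in both factors; linear in ``G``.
    """
    if not isinstance(G, Tensor):
        G = Tensor(G)
    if G.data.shape != F.shape_tag:
        raise ValueError(
            f"gradient shape {G.data.shape} does not match the factor pair for "
            f"parameter tensor of shape {F.shape_tag}"
        )
    return matmul(matmul(F.left, G), F.right)


def identity_factors(m: int, n: int, requires_grad: bool = False) -> FactorPair:
    """Identity preconditioner for an ``m×n`` gradient matrix."""
    if m < 1 or n < 1:
        raise ValueError(f"factor dimensions must be >= 1, got ({m}, {n})")
    return FactorPair(
        left=Tensor(np.eye(m), requires_grad=requires_grad),
        right=Tensor(np.eye(n), requires_grad=requires_grad),
        shape_tag=(m, n),
    )


def vec(M: np.ndarray) -> np.ndarray:
    """Column-major vectorisation, the convention under which
    ``vec(L G R) = (Rᵀ ⊗ L) vec(G)`` holds."""
    return np.asarray(M).flatten(order="F")
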