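"""Multi-modal factorized bilinear (MFB) pooling.

Two embeddings x1 in R^m and x2 in R^n are projected by factor matrices
U (m x k*o) and V (n x k*o); the elementwise product of the projections is
sum-pooled over consecutive groups of k, giving a fused vector z in R^o:

    z_j = sum_{t=1..k} (U^T x1)_{(j-1)k+t} * (V^T x2)_{(j-1)k+t}

This equals the bilinear form x1^T W_j x2 with W_j the rank-k matrix
U_j V_j^T built from the j-th factor slices.  z then passes through signed
square-root ("power") normalization sign(z)*sqrt(|z|) and l2 normalization
z/||z||, so the output has unit l2 norm unless z = 0, in which case it is 0.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .layers import Layer

__all__ = ["mfb_fuse", "MFBFusion"]

_L2_EPS = 1e-12      # guard in the l2 division
_GRAD_EPS = 1e-6     # guard for the power-norm derivative at z = 0


def _mfb_core(x1: np.ndarray, x2: np.ndarray, U: np.ndarray, V: np.ndarray,
              k: int, o: int):
    p1 = x1 @ U
    p2 = x2 @ V
    h = p1 * p2
    z = h.reshape(-1, o, k).sum(axis=2)
    return p1, p2, z


def _power_l2(z: np.ndarray) -> np.ndarray:
    y = np.sign(z) * np.sqrt(np.abs(z))
    norm = np.linalg.norm(y, axis=1, keepdims=True)
    return y / np.maximum(norm, _L2_EPS)


def mfb_fuse(x1, x2, U, V, k: int, o: int) -> np.ndarray:
    """Fuse two embeddings (single vectors or batches) into R^o.

    ``U`` has shape (m, k*o), ``V`` (n, k*o).  Accepts 1-D inputs (returns a
    1-D output) or matching 2-D batches.
    """
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    single = x1.ndim == 1
    if single:
        x1, x2 = x1[None, :], x2[None, :]
    if U.shape != (x1.shape[1], k * o) or V.shape != (x2.shape[1], k * o):
        raise ValueError(
            f"factor shapes {U.shape}/{V.shape} inconsistent with "
            f"m={x1.shape[1]}, n={x2.shape[1]}, k*o={k * o}"
        )
    _, _, z = _mfb_core(x1, x2, np.asarray(U, float), np.asarray(V, float), k, o)
    out = _power_l2(z)
    return out[0] if single else out


class MFBFusion(Layer):
    """MFB pooling as a trainable layer with backprop.

    forward takes ``(x1, x2)`` of shapes (B, m) and (B, n).
    backward returns ``(dx1, dx2)``.
    """

    def __init__(self, m: int, n: int, k: int, o: int, rng: np.random.Generator):
        self.m, self.n, self.k, self.o = m, n, k, o
        ko = k * o
        # Xavier-ish init on the factors: keeps products O(1) pre-pooling
        self.U = rng.normal(0.0, np.sqrt(1.0 / m), size=(m, ko)).astype(np.float32)
        self.V = rng.normal(0.0, np.sqrt(1.0 / n), size=(n, ko)).astype(np.float32)
        self.dU = np.zeros_like(self.U)
        self.dV = np.zeros_like(self.V)

    def params(self):
        return [("U", self.U, self.dU), ("V", self.V, self.dV)]

    def forward(self, xs: Tuple[np.ndarray, np.ndarray], train: bool = False):
        x1, x2 = xs
        self._x1, self._x2 = x1, x2
        p1, p2, z = _mfb_core(x1, x2, self.U, self.V, self.k, self.o)
        self._p1, self._p2, self._z = p1, p2, z
        y = np.sign(z) * np.sqrt(np.abs(z))
        norm = np.linalg.norm(y, axis=1, keepdims=True)
        self._y, self._norm = y, np.maximum(norm, _L2_EPS)
        return (y / self._norm).astype(np.float32)

    def backward(self, grad):
        y, norm = self._y, self._norm
        out = y / norm
        # l2 normalization: d/dy (y / ||y||)
        gy = (grad - out * (grad * out).sum(axis=1, keepdims=True)) / norm
        # power normalization: dy/dz = 0.5 / sqrt(|z|)
        gz = gy * (0.5 / np.maximum(np.sqrt(np.abs(self._z)), _GRAD_EPS))
        gh = np.repeat(gz, self.k, axis=1)
        gp1 = (gh * self._p2).astype(np.float32)
        gp2 = (gh * self._p1).astype(np.float32)
        self.dU[...] = self._x1.T @ gp1
        self.dV[...] = self._x2.T @ gp2
        return gp1 @ self.U.T, gp2 @ self.V.T
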