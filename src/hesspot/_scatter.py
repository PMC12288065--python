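"""Assembly of per-term gradients/Hessians into full Cartesian arrays.

Interaction terms are functions of displacement vectors (u = x_j - x_i for
pairs; u = x_i - x_c, v = x_k - x_c for angle triples).  These helpers map
local derivatives of such terms onto (n, 3) gradient and (3n, 3n) Hessian
accumulators.  Shared by the analytic reference surfaces and by nothing
else; the descriptor keeps its own channel-resolved scatter.
"""

from __future__ import annotations

import numpy as np


def scatter_pair(n: int, I: np.ndarray, J: np.ndarray,
                 g: np.ndarray | None, h: np.ndarray | None,
                 grad: np.ndarray | None, hess_flat: np.ndarray | None) -> None:
    """Accumulate pair-term derivatives (w.r.t. u = x_J - x_I).

    g: (P, 3); h: (P, 3, 3); grad: (n, 3); hess_flat: (n*n, 3, 3) viewed
    as atom-block matrix.
    """
    if grad is not None and g is not None:
        np.add.at(grad, J, g)
        np.add.at(grad, I, -g)
    if hess_flat is not None and h is not None:
        np.add.at(hess_flat, J * n + J, h)
        np.add.at(hess_flat, I * n + I, h)
        np.add.at(hess_flat, I * n + J, -h)
        np.add.at(hess_flat, J * n + I, -np.swapaxes(h, -1, -2))


def scatter_triple(n: int, I: np.ndarray, C: np.ndarray, K: np.ndarray,
                   g: np.ndarray | None, h: np.ndarray | None,
                   grad: np.ndarray | None, hess_flat: np.ndarray | None) -> None:
    """Accumulate triple-term derivatives w.r.t. (u, v) = (x_I - x_C, x_K - x_C)."""
    if grad is not None and g is not None:
        gu, gv = g[:, :3], g[:, 3:]
        np.add.at(grad, I, gu)
        np.add.at(grad, K, gv)
        np.add.at(grad, C, -(gu + gv))
    if hess_flat is not None and h is not None:
        huu = h[:, :3, :3]
        huv = h[:, :3, 3:]
        hvu = h[:, 3:, :3]
        hvv = h[:, 3:, 3:]
        np.add.at(hess_flat, I * n + I, huu)
        np.add.at(hess_flat, K * n + K, hvv)
        np.add.at(hess_flat, I * n + K, huv)
        np.add.at(hess_flat, K * n + I, hvu)
        np.add.at(hess_flat, C * n + C, huu + huv + hvu + hvv)
        np.add.at(hess_flat, I * n + C, -(huu + huv))
        np.add.at(hess_flat, C * n + I, -(huu + hvu))
        np.add.at(hess_flat, K * n + C, -(hvu + hvv))
        np.add.at(hess_flat, C * n + K, -(huv + hvv))


def hess_accumulator(n: int):
    """Fresh (n*n, 3, 3) block accumulator."""
    return np.zeros((n * n, 3, 3))


def hess_from_blocks(hess_flat: np.ndarray, n: int) -> np.ndarray:
    """(n*n, 3, 3) block accumulator -> dense (3n, 3n)."""
    return (hess_flat.reshape(n, n, 3, 3)
            .transpose(0, 2, 1, 3)
            .reshape(3 * n, 3 * n))
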