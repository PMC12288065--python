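"""Feed-forward atomic networks evaluated on second-order jets.

A per-element network maps an atom's descriptor vector to an atomic energy
partition.  To train on forces and Hessians, the network must be evaluated
not just on descriptor *values* but on their first and second coordinate
derivatives: propagating the (value, gradient, Hessian) triple through
every layer yields the predicted energy together with its exact first and
second derivatives with respect to the Cartesian coordinates.

For a hidden layer h = tanh(a), a = W g + b, the jet transforms as

    value     t        = tanh(a)
    gradient  g_out    = phi'(a) * g_a
    Hessian   H_out    = phi'(a) * H_a + phi''(a) * g_a (x) g_a

and the reverse pass (needed for the loss gradient with respect to the
weights, a third-order mixed derivative overall) is derived by
differentiating these identities; it requires phi''' as well.  tanh is
C-infinity, which is the reason it is the default activation: a kinked
activation would make the Hessian targets unlearnable.

Shapes: values (na, U); gradients (na, D, U); Hessians (na, D, D, U) with
D the padded coordinate dimension of the batch.
"""

from __future__ import annotations

import numpy as np


def _mm(X, W):
    """Matmul over the last axis, reshaped to one 2-D GEMM."""
    shape = X.shape
    return (X.reshape(-1, shape[-1]) @ W).reshape(*shape[:-1], W.shape[1])


def _contract_lu(X, dY):
    """einsum '...l,...u->lu' as one GEMM."""
    return X.reshape(-1, X.shape[-1]).T @ dY.reshape(-1, dY.shape[-1])


def init_params(rng: np.random.Generator, layer_sizes: list[int]):
    """Xavier/Glorot initialization; final layer is linear with one output."""
    params = []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        W = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        params.append((W, b))
    return params


def mlp_jet_forward(params, V, Gr=None, Hs=None):
    """Evaluate the scalar MLP on jets.

    Returns (f, fg, fh, cache): per-atom scalar output (na,), its gradient
    (na, D) and Hessian (na, D, D) w.r.t. whatever directions the input
    jets carry; fg/fh are None when Gr/Hs are None.
    """
    cache = []
    n_layers = len(params)
    for li, (W, b) in enumerate(params):
        A = V @ W + b
        Ga = None if Gr is None else _mm(Gr, W)
        Ha = None if Hs is None else _mm(Hs, W)
        if li == n_layers - 1:   # linear output layer
            cache.append(("linear", V, Gr, Hs))
            f = A[:, 0]
            fg = None if Ga is None else Ga[..., 0]
            fh = None if Ha is None else Ha[..., 0]
            return f, fg, fh, cache
        t = np.tanh(A)
        p = 1.0 - t * t
        q = -2.0 * t * p
        Vn = t
        Gn = None if Ga is None else p[:, None, :] * Ga
        Hn = None
        if Ha is not None:
            Hn = (p[:, None, None, :] * Ha
                  + q[:, None, None, :] * Ga[:, :, None, :] * Ga[:, None, :, :])
        cache.append(("tanh", V, Gr, Hs, t, p, q, Ga, Ha))
        V, Gr, Hs = Vn, Gn, Hn
    raise AssertionError("unreachable")


def mlp_jet_backward(params, cache, df, dfg=None, dfh=None):
    """Gradient of a scalar loss w.r.t. all weights/biases.

    df/dfg/dfh are the loss gradients w.r.t. the forward outputs f/fg/fh.
    Returns a list of (dW, db) matching ``params``.
    """
    grads: list = [None] * len(params)

    # output (linear) layer
    W, _b = params[-1]
    _, V, Gr, Hs = cache[-1]
    dA = df[:, None]                              # (na, 1)
    dW = V.T @ dA
    db = dA.sum(axis=0)
    dV = dA @ W.T
    dGr = dHs = None
    if dfg is not None:
        dGa = dfg[..., None]                      # (na, D, 1)
        dW += _contract_lu(Gr, dGa)
        dGr = _mm(dGa, W.T)
    if dfh is not None:
        dHa = dfh[..., None]
        dW += _contract_lu(Hs, dHa)
        dHs = _mm(dHa, W.T)
    grads[-1] = (dW, db)

    for li in range(len(params) - 2, -1, -1):
        W, _b = params[li]
        _, V, Gr, Hs, t, p, q, Ga, Ha = cache[li]
        r = p * (6.0 * t * t - 2.0)               # phi'''
        dA = dV * p
        dGa = dHa = None
        if dGr is not None:
            dA += q * (dGr * Ga).sum(axis=1)
            dGa = p[:, None, :] * dGr
        if dHs is not None:
            t1 = (dHs * Ga[:, :, None, :]).sum(axis=1)        # (a, e, u)
            dA += (q * (dHs * Ha).sum(axis=(1, 2))
                   + r * (t1 * Ga).sum(axis=1))
            sym = dHs + np.swapaxes(dHs, 1, 2)
            extra = q[:, None, :] * (sym * Ga[:, None, :, :]).sum(axis=2)
            dGa = extra if dGa is None else dGa + extra
            dHa = p[:, None, None, :] * dHs
        dW = V.T @ dA
        db = dA.sum(axis=0)
        dV = dA @ W.T
        if dGa is not None:
            dW += _contract_lu(Gr, dGa)
            dGr = _mm(dGa, W.T)
        else:
            dGr = None
        if dHa is not None:
            dW += _contract_lu(Hs, dHa)
            dHs = _mm(dHa, W.T)
        else:
            dHs = None
        grads[li] = (dW, db)
    return grads


class Adam:
    """Adaptive-moment gradient descent over a flat list of arrays."""

    def __init__(self, arrays, lr=1e-2, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, arrays, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for a, g, m, v in zip(arrays, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            a -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
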