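"""Second-order forward-mode differentiation ("jets").

A :class:`Jet` carries a value array of shape ``S`` together with its
gradient ``S + (m,)`` and Hessian ``S + (m, m)`` with respect to ``m``
seed directions.  Propagating jets through an elementwise computation
yields exact (chain-rule) first and second derivatives — this is the
engine behind both the analytic reference surfaces and the nested
differentiation of the learned potential (force = first order, Hessian =
second order of the energy output).

Orders 0/1/2 are supported so force-only paths skip the quadratic cost.
"""

from __future__ import annotations

import numpy as np


class Jet:
    __slots__ = ("v", "g", "h", "order")

    def __init__(self, v, g=None, h=None):
        self.v = np.asarray(v, dtype=float)
        self.g = g
        self.h = h
        self.order = 0 if g is None else (1 if h is None else 2)

    # --- constructors -------------------------------------------------
    @staticmethod
    def variable(values: np.ndarray, seeds: np.ndarray, order: int = 2,
                 seeds2: np.ndarray | None = None) -> "Jet":
        """A linear function of the seed directions.

        ``values`` has shape S; ``seeds`` shape S+(m,) gives d(value)/d(dir).
        Second derivatives of a linear seed map are zero.
        """
        values = np.asarray(values, dtype=float)
        seeds = np.asarray(seeds, dtype=float)
        if order == 0:
            return Jet(values)
        if order == 1:
            return Jet(values, seeds)
        m = seeds.shape[-1]
        h = np.zeros(values.shape + (m, m)) if seeds2 is None else seeds2
        return Jet(values, seeds, h)

    @staticmethod
    def constant(values, like: "Jet") -> "Jet":
        values = np.asarray(values, dtype=float)
        if like.order == 0:
            return Jet(values)
        m = like.g.shape[-1]
        g = np.zeros(values.shape + (m,))
        if like.order == 1:
            return Jet(values, g)
        return Jet(values, g, np.zeros(values.shape + (m, m)))

    # --- helpers ------------------------------------------------------
    def _chain(self, f, f1, f2) -> "Jet":
        """Apply a scalar function elementwise: f(v), f'(v), f''(v) given."""
        if self.order == 0:
            return Jet(f)
        g = f1[..., None] * self.g
        if self.order == 1:
            return Jet(f, g)
        outer = self.g[..., :, None] * self.g[..., None, :]
        h = f1[..., None, None] * self.h + f2[..., None, None] * outer
        return Jet(f, g, h)

    @staticmethod
    def _as_jet(other, like: "Jet") -> "Jet":
        if isinstance(other, Jet):
            return other
        return Jet.constant(np.asarray(other, dtype=float), like)

    # --- arithmetic ---------------------------------------------------
    def __add__(self, other):
        if not isinstance(other, Jet):
            j = Jet(self.v + other, self.g, self.h)
            return j
        order = min(self.order, other.order)
        v = self.v + other.v
        if order == 0:
            return Jet(v)
        g = self.g + other.g
        if order == 1:
            return Jet(v, g)
        return Jet(v, g, self.h + other.h)

    __radd__ = __add__

    def __neg__(self):
        return Jet(-self.v, None if self.g is None else -self.g,
                   None if self.h is None else -self.h)

    def __sub__(self, other):
        return self + (-other if isinstance(other, Jet) else -np.asarray(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if not isinstance(other, Jet):
            c = np.asarray(other, dtype=float)
            return Jet(
                self.v * c,
                None if self.g is None else self.g * c[..., None],
                None if self.h is None else self.h * c[..., None, None],
            )
        order = min(self.order, other.order)
        v = self.v * other.v
        if order == 0:
            return Jet(v)
        g = self.g * other.v[..., None] + other.g * self.v[..., None]
        if order == 1:
            return Jet(v, g)
        cross = (self.g[..., :, None] * other.g[..., None, :]
                 + other.g[..., :, None] * self.g[..., None, :])
        h = (self.h * other.v[..., None, None]
             + other.h * self.v[..., None, None] + cross)
        return Jet(v, g, h)

    __rmul__ = __mul__

    def reciprocal(self) -> "Jet":
        inv = 1.0 / self.v
        return self._chain(inv, -inv * inv, 2.0 * inv * inv * inv)

    def __truediv__(self, other):
        if isinstance(other, Jet):
            return self * other.reciprocal()
        return self * (1.0 / np.asarray(other, dtype=float))

    def __rtruediv__(self, other):
        return self.reciprocal() * other

    def __pow__(self, p):
        if isinstance(p, int) and p >= 2:
            v = self.v ** p
            return self._chain(v, p * self.v ** (p - 1),
                               p * (p - 1) * self.v ** (p - 2))
        v = self.v ** p
        return self._chain(v, p * self.v ** (p - 1.0),
                           p * (p - 1.0) * self.v ** (p - 2.0))

    # --- transcendental -----------------------------------------------
    def exp(self) -> "Jet":
        e = np.exp(self.v)
        return self._chain(e, e, e)

    def sqrt(self) -> "Jet":
        s = np.sqrt(self.v)
        return self._chain(s, 0.5 / s, -0.25 / (s * self.v))

    def cos(self) -> "Jet":
        return self._chain(np.cos(self.v), -np.sin(self.v), -np.cos(self.v))

    def sin(self) -> "Jet":
        return self._chain(np.sin(self.v), np.cos(self.v), -np.sin(self.v))

    def arccos(self, clip: float = 1e-9) -> "Jet":
        # clipped away from +-1; geometries probed by this package keep
        # angles away from 0/pi so the clip never activates in practice.
        c = np.clip(self.v, -1.0 + clip, 1.0 - clip)
        s = np.sqrt(1.0 - c * c)
        return self._chain(np.arccos(c), -1.0 / s, -c / (s * s * s))

    def tanh(self) -> "Jet":
        t = np.tanh(self.v)
        p = 1.0 - t * t
        return self._chain(t, p, -2.0 * t * p)

    def sum(self, axis=None) -> "Jet":
        # axes refer to the *value* shape; normalize so the trailing
        # direction axes of g/h are untouched.
        if axis is None:
            axes = tuple(range(self.v.ndim))
        elif isinstance(axis, int):
            axes = (axis % self.v.ndim,)
        else:
            axes = tuple(a % self.v.ndim for a in axis)
        v = self.v.sum(axis=axes)
        if self.order == 0:
            return Jet(v)
        g = self.g.sum(axis=axes)
        if self.order == 1:
            return Jet(v, g)
        return Jet(v, g, self.h.sum(axis=axes))


def dot3(a: Jet, b: Jet) -> Jet:
    """Dot product of two 3-vector jets stored with component axis last
    in the *value* shape S+(3,): returns a scalar jet of shape S."""
    return (a * b).sum(axis=-1)


def vector_jet(components: list[Jet]) -> Jet:
    """Stack scalar jets (same shape) into a jet with a trailing axis."""
    v = np.stack([c.v for c in components], axis=-1)
    if components[0].order == 0:
        return Jet(v)
    g = np.stack([c.g for c in components], axis=-2)
    if components[0].order == 1:
        return Jet(v, g)
    h = np.stack([c.h for c in components], axis=-3)
    return Jet(v, g, h)
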