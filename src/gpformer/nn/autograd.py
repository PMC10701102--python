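"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the prediction network needs: broadcasted
arithmetic, matrix products, the GELU nonlinearity, softmax, layer
normalization, dropout, a same-padded 1-D convolution, a replicate-padded
moving average, and the FFT-based circular-correlation / delayed-aggregation
pair used by autocorrelation attention.  Everything is float64; gradients
are validated against central finite differences in the test suite.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @classmethod
    def _node(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._node(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._node(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._node(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(
                    _unbroadcast(np.matmul(g, np.swapaxes(other.data, -1, -2)), self.data.shape)
                )
            if other.requires_grad:
                other._accum(
                    _unbroadcast(np.matmul(np.swapaxes(self.data, -1, -2), g), other.data.shape)
                )

        return Tensor._node(np.matmul(self.data, other.data), (self, other), bwd)

    def __pow__(self, n: float):
        n = float(n)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * n * np.power(self.data, n - 1.0))

        return Tensor._node(np.power(self.data, n), (self,), bwd)

    # -- shape -------------------------------------------------------------

    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._node(self.data.reshape(*shape), (self,), bwd)

    # -- elementwise nonlinearities ----------------------------------------

    def tanh(self):
        t = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (1.0 - t * t))

        return Tensor._node(t, (self,), bwd)

    def abs(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(g * np.sign(self.data))

        return Tensor._node(np.abs(self.data), (self,), bwd)

    def gelu(self):
        """Exact-erf GELU: x * Phi(x)."""
        from scipy.special import erf

        x = self.data
        phi_cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (phi_cdf + x * pdf))

        return Tensor._node(x * phi_cdf, (self,), bwd)

    # -- reductions ----------------------------------------------------------

    def mean(self):
        size = self.data.size

        def bwd(g):
            if self.requires_grad:
                self._accum(np.full_like(self.data, float(g) / size))

        return Tensor._node(self.data.mean(), (self,), bwd)

    def sum(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(np.full_like(self.data, float(g)))

        return Tensor._node(self.data.sum(), (self,), bwd)

    # -- normalization, attention pieces -------------------------------------

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            if self.requires_grad:
                inner = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - inner))

        return Tensor._node(s, (self,), bwd)

    def layer_norm(self, eps: float = 1e-5):
        """Normalize the last axis to zero mean / unit variance (no affine)."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv

        def bwd(g):
            if self.requires_grad:
                gm = g.mean(axis=-1, keepdims=True)
                gx = (g * xhat).mean(axis=-1, keepdims=True)
                self._accum(inv * (g - gm - xhat * gx))

        return Tensor._node(xhat, (self,), bwd)

    def dropout(self, p: float, rng: np.random.Generator | None):
        """Inverted dropout; identity when ``rng`` is None (evaluation mode)."""
        if rng is None or p <= 0.0:
            return self
        mask = ((rng.random(self.data.shape) >= p) / (1.0 - p)).astype(self.data.dtype)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._node(self.data * mask, (self,), bwd)

    # -- sequence operations --------------------------------------------------

    def conv1d(self, weight: "Tensor", bias: "Tensor"):
        """Same-padded 1-D convolution over the last axis.

        self: (B, C, L); weight: (D, C, K); bias: (D,) -> output (B, L, D).
        """
        x, W = self.data, weight.data
        B, C, L = x.shape
        D, Cw, K = W.shape
        if C != Cw:
            raise ValueError(f"input has {C} channels but kernel expects {Cw}")
        pl = (K - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pl, K - 1 - pl)))
        win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # (B,C,L,K)
        out = np.einsum("bclk,dck->bld", win, W) + bias.data

        def bwd(g):  # g: (B, L, D)
            if weight.requires_grad:
                weight._accum(np.einsum("bclk,bld->dck", win, g))
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 1)))
            if self.requires_grad:
                gxp = np.zeros_like(xp)
                contrib = np.einsum("bld,dck->bclk", g, W)
                for k in range(K):
                    gxp[:, :, k : k + L] += contrib[:, :, :, k]
                self._accum(gxp[:, :, pl : pl + L])

        return Tensor._node(out, (self, weight, bias), bwd)

    def moving_average(self, window: int):
        """Centered moving average along axis 1 with replicate edge padding.

        self: (B, L, D); ``window`` odd.  Length-preserving; the trend half
        of a series decomposition.
        """
        if window % 2 != 1 or window < 1:
            raise ValueError("window must be odd and >= 1")
        x = self.data
        B, L, D = x.shape
        h = window // 2
        xp = np.concatenate(
            [np.repeat(x[:, :1], h, axis=1), x, np.repeat(x[:, -1:], h, axis=1)], axis=1
        )
        cs = np.cumsum(xp, axis=1)
        zero = np.zeros((B, 1, D), dtype=x.dtype)
        cs = np.concatenate([zero, cs], axis=1)
        trend = (cs[:, window:] - cs[:, :-window]) / window

        def bwd(g):  # g: (B, L, D)
            if not self.requires_grad:
                return
            # adjoint of valid-mode uniform filtering on the padded series:
            # full correlation of g with the uniform kernel ...
            pad = np.zeros((B, window - 1, D), dtype=g.dtype)
            gz = np.concatenate([pad, g, pad], axis=1)
            c = np.cumsum(gz, axis=1)
            c = np.concatenate([zero, c], axis=1)
            gp = (c[:, window:] - c[:, :-window]) / window  # (B, L + 2h, D)
            # ... then fold padded-edge gradients onto the replicated cells
            gx = gp[:, h : h + L].copy()
            gx[:, 0] += gp[:, :h].sum(axis=1)
            gx[:, -1] += gp[:, h + L :].sum(axis=1)
            self._accum(gx)

        return Tensor._node(trend, (self,), bwd)

    def circ_corr_scores(self, other: "Tensor"):
        """Lag scores of circular cross-correlation, averaged over channels.

        self (Q), other (K): (B, L, D).  Returns (B, L) with
        score(tau) = mean_d sum_s Q[(s+tau) % L, d] * K[s, d], evaluated via
        rFFT with the inverse transform carrying the 1/L factor.
        """
        q, k = self.data, other.data
        if q.shape != k.shape:
            raise ValueError("query and key must have identical shapes")
        B, L, D = q.shape
        fq = np.fft.rfft(q, axis=1)
        fk = np.fft.rfft(k, axis=1)
        ar = np.fft.irfft(fq * np.conj(fk), n=L, axis=1)  # (B, L, D)
        out = ar.mean(axis=2)

        def bwd(g):  # g: (B, L)
            gc = g[:, :, None] / D
            fg = np.fft.rfft(gc, axis=1)
            if self.requires_grad:
                # d score(tau) / d q[u] = k[(u - tau) % L]: circular convolution
                self._accum(np.fft.irfft(fg * np.fft.rfft(k, axis=1), n=L, axis=1))
            if other.requires_grad:
                # d score(tau) / d k[s] = q[(s + tau) % L]: correlation of q with g
                other._accum(
                    np.fft.irfft(np.fft.rfft(q, axis=1) * np.conj(fg), n=L, axis=1)
                )

        return Tensor._node(out, (self, other), bwd)

    def delay_aggregate(self, delays: np.ndarray, weights: "Tensor"):
        """Weighted sum of circularly time-delayed copies of ``self``.

        self (V): (B, L, D); delays: int array (B, k) of lags; weights:
        Tensor (B, k).  out[b, t] = sum_j weights[b, j] * V[b, (t + tau_bj) % L].
        """
        v = self.data
        B, L, D = v.shape
        t = np.arange(L)[None, None, :]
        b_ix = np.arange(B)[:, None, None]
        idx = (t + delays[:, :, None]) % L  # (B, k, L)
        rolled = v[b_ix, idx]  # (B, k, L, D)
        out = np.einsum("bkld,bk->bld", rolled, weights.data)

        def bwd(g):  # g: (B, L, D)
            if weights.requires_grad:
                weights._accum(np.einsum("bld,bkld->bk", g, rolled))
            if self.requires_grad:
                # dL/dv[u] = sum_j w_j g[(u - tau_j) % L]: another gather
                inv = (t - delays[:, :, None]) % L
                self._accum(np.einsum("bkld,bk->bld", g[b_ix, inv], weights.data))

        return Tensor._node(out, (self, weights), bwd)

    def take_lags(self, delays: np.ndarray):
        """Gather per-sample lag scores: self (B, L), delays (B, k) -> (B, k)."""
        s = self.data

        def bwd(g):
            if self.requires_grad:
                gs = np.zeros_like(s)
                np.add.at(gs, (np.arange(s.shape[0])[:, None], delays), g)
                self._accum(gs)

        return Tensor._node(np.take_along_axis(s, delays, axis=1), (self,), bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)
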