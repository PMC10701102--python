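"""The GPformer network: convolutional SNP embedding with sinusoidal
positional features, autocorrelation-attention encoder blocks with series
decomposition, and a flatten-plus-linear regression head.

Attention here scores *lags* rather than position pairs: the circular
cross-correlation of query and key (computed via FFT) is evaluated at every
delay tau, the top k = max(1, floor(c * ln L)) delays are kept, and the
output is the softmax-weighted sum of circularly time-delayed copies of the
value sequence.  This gives sequence-level aggregation at O(L log L) cost,
which matters because SNP sequences are far longer than typical text
inputs.

The module-level functions (`positional_encoding`,
`autocorrelation_scores`, `topk_delays`, `series_decomposition`, `gelu`,
...) are plain-numpy reference implementations of the individual
operations; :class:`GPformer` composes the same math through the autodiff
engine in :mod:`gpformer.nn` so the network is trainable.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.special import erf

from .io import EncodedInput
from .nn.autograd import Tensor

__all__ = [
    "ModelConfig",
    "GPformer",
    "positional_encoding",
    "autocorrelation_scores",
    "topk_delays",
    "autocorrelation_attention",
    "series_decomposition",
    "gelu",
    "gelu_tanh",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    d_model : even embedding width (length of the positional feature).
    n_blocks : number of encoder blocks.
    c_factor : top-k factor c in k = max(1, floor(c * ln L)).
    decomp_window : odd moving-average window of the series decomposition.
    dropout : dropout fraction used in training mode.
    embed_kernel : width of the SNP feature-embedding convolution.
    use_kgm : whether 3 GWAS-weighted one-hot channels are concatenated
        to the base encoding channels before the embedding convolution.
    base_encoding : "additive" (1 channel) or "onehot" (3 channels).
    index_positions : replace physical bp coordinates by 0..L-1 in the
        positional encoding (the fallback when no map is available).
    precision : parameter/activation dtype; "float64" keeps the op-level
        contracts exact, "float32" roughly halves training cost on long
        marker sequences (positional features are still computed in double
        precision before casting).
    """

    d_model: int = 64
    n_blocks: int = 1
    c_factor: float = 2.0
    decomp_window: int = 25
    dropout: float = 0.1
    embed_kernel: int = 3
    use_kgm: bool = False
    base_encoding: str = "additive"
    index_positions: bool = False
    precision: str = "float64"

    def __post_init__(self) -> None:
        if self.precision not in ("float32", "float64"):
            raise ValueError("precision must be 'float32' or 'float64'")
        if self.d_model < 2 or self.d_model % 2 != 0:
            raise ValueError("d_model must be even and >= 2")
        if self.decomp_window < 1 or self.decomp_window % 2 != 1:
            raise ValueError("decomp_window must be odd and >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.c_factor <= 0:
            raise ValueError("c_factor must be positive")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.base_encoding not in ("additive", "onehot"):
            raise ValueError("base_encoding must be 'additive' or 'onehot'")

    @property
    def in_channels(self) -> int:
        base = 1 if self.base_encoding == "additive" else 3
        return base + (3 if self.use_kgm else 0)


# ---------------------------------------------------------------------------
# reference implementations of the individual operations
# ---------------------------------------------------------------------------

def positional_encoding(positions: np.ndarray, d_model: int) -> np.ndarray:
    """Sinusoidal positional features evaluated at physical locations t.

    pe[t, 2k] = sin(w_k t), pe[t, 2k+1] = cos(w_k t) with
    w_k = 1 / 10000^(2k / d_model).  Computed in double precision so that
    base-pair coordinates up to ~1e8 keep sub-radian phase error.
    """
    if d_model % 2 != 0:
        raise ValueError("d_model must be even")
    t = np.asarray(positions, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("positions must be non-negative")
    k = np.arange(d_model // 2, dtype=np.float64)
    omega = 1.0 / np.power(10000.0, 2.0 * k / d_model)
    ang = t[:, None] * omega[None, :]
    pe = np.empty((t.size, d_model))
    pe[:, 0::2] = np.sin(ang)
    pe[:, 1::2] = np.cos(ang)
    return pe


def autocorrelation_scores(q: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Per-lag circular cross-correlation AR(tau) = sum_s q[(s+tau) % L] k[s].

    Computed as irfft(rfft(q) * conj(rfft(k))); works on 1-D arrays or on
    any (..., L) stack along the last axis.
    """
    q = np.asarray(q, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    if q.shape != k.shape:
        raise ValueError("q and k must have the same length")
    L = q.shape[-1]
    return np.fft.irfft(np.fft.rfft(q, axis=-1) * np.conj(np.fft.rfft(k, axis=-1)), n=L, axis=-1)


def num_delays(c: float, L: int) -> int:
    """k = max(1, floor(c * ln L)) — the number of lags kept by attention."""
    return max(1, int(math.floor(c * math.log(L))))


def topk_delays(ar: np.ndarray, c: float, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Select the k highest-scoring lags and their softmax weights.

    Ties break toward the smaller lag.  Returns ``(delays, weights)`` with
    ``weights`` the softmax over exactly the selected scores.
    """
    ar = np.asarray(ar, dtype=np.float64)
    if L < 2:
        raise ValueError("need L >= 2")
    if not np.isfinite(ar).any():
        raise FloatingPointError("all lag scores are non-finite")
    k = num_delays(c, L)
    order = np.argsort(-ar, axis=-1, kind="stable")  # stable -> smaller lag wins ties
    delays = order[..., :k]
    sel = np.take_along_axis(ar, delays, axis=-1)
    z = sel - sel.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return delays, e / e.sum(axis=-1, keepdims=True)


def autocorrelation_attention(
    q: np.ndarray, k: np.ndarray, v: np.ndarray, c: float = 2.0
) -> np.ndarray:
    """Numpy evaluation of the full attention operation on (B, L, D) arrays.

    Lag scores are averaged over the feature channels, delays are shared
    across channels per sample, and the output is
    sum_j weight_j * roll(v, tau_j) with softmax weights over the selected
    lag scores.
    """
    q, k, v = (np.atleast_3d(np.asarray(a, dtype=np.float64)) for a in (q, k, v))
    B, L, D = v.shape
    ar = autocorrelation_scores(
        np.moveaxis(q, 1, 2), np.moveaxis(k, 1, 2)
    ).mean(axis=1)  # (B, L)
    delays, weights = topk_delays(ar, c, L)
    out = np.zeros_like(v)
    t = np.arange(L)[None, :]
    for j in range(delays.shape[1]):
        idx = (t + delays[:, j : j + 1]) % L
        out += weights[:, j, None, None] * np.take_along_axis(v, idx[:, :, None], axis=1)
    return out


def series_decomposition(x: np.ndarray, window: int, axis: int = -1) -> tuple[np.ndarray, np.ndarray]:
    """Split a sequence into (residual, trend) with a replicate-padded
    moving average of odd ``window``; residual + trend == x exactly."""
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be odd and >= 1")
    x = np.asarray(x, dtype=np.float64)
    x_m = np.moveaxis(x, axis, -1)
    h = window // 2
    xp = np.concatenate(
        [np.repeat(x_m[..., :1], h, axis=-1), x_m, np.repeat(x_m[..., -1:], h, axis=-1)],
        axis=-1,
    )
    cs = np.cumsum(xp, axis=-1)
    cs = np.concatenate([np.zeros_like(cs[..., :1]), cs], axis=-1)
    trend = (cs[..., window:] - cs[..., :-window]) / window
    trend = np.moveaxis(trend, -1, axis)
    return x - trend, trend


def gelu(x):
    """Exact Gaussian error linear unit: x * Phi(x)."""
    x = np.asarray(x, dtype=np.float64)
    return x * 0.5 * (1.0 + erf(x / math.sqrt(2.0)))


def gelu_tanh(x):
    """The tanh approximation 0.5 x (1 + tanh(sqrt(2/pi)(x + 0.044715 x^3)))."""
    x = np.asarray(x, dtype=np.float64)
    return 0.5 * x * (1.0 + np.tanh(math.sqrt(2.0 / math.pi) * (x + 0.044715 * x**3)))


# ---------------------------------------------------------------------------
# the trainable network
# ---------------------------------------------------------------------------

class GPformer:
    """Embedding -> n encoder blocks -> flatten -> linear phenotype head.

    The sequence length L is fixed at construction (the regression head is
    a linear map on the flattened L x d_model features).  All parameters
    are float64 numpy arrays wrapped in autodiff tensors; initialization is
    fan-in-scaled Gaussian from the given seed.
    """

    def __init__(
        self,
        cfg: ModelConfig,
        n_markers: int,
        positions: np.ndarray | None = None,
        seed: int = 0,
    ):
        self.cfg = cfg
        self.L = int(n_markers)
        if positions is None or cfg.index_positions:
            positions = np.arange(self.L)
        positions = np.asarray(positions)
        if positions.shape != (self.L,):
            raise ValueError("one position per marker required")
        self.positions = positions.astype(np.float64)
        self.dtype = np.dtype(cfg.precision)
        self.pe = positional_encoding(self.positions, cfg.d_model).astype(self.dtype)
        self.k_delays = num_delays(cfg.c_factor, self.L)
        rng = np.random.default_rng(seed)
        D, C, K = cfg.d_model, cfg.in_channels, cfg.embed_kernel

        def init(*shape, fan_in):
            w = rng.standard_normal(shape) / math.sqrt(fan_in)
            return Tensor(w.astype(self.dtype), requires_grad=True)

        def zeros(*shape, fill=0.0):
            return Tensor(np.full(shape, fill, dtype=self.dtype), requires_grad=True)

        self.W_emb = init(D, C, K, fan_in=C * K)
        self.b_emb = zeros(D)
        self.blocks = []
        for _ in range(cfg.n_blocks):
            self.blocks.append(
                {
                    "Wc": init(D, D, fan_in=D),
                    "bc": zeros(D),
                    "ln_g": zeros(D, fill=1.0),
                    "ln_b": zeros(D),
                }
            )
        self.W_head = init(self.L * D, 1, fan_in=self.L * D)
        self.b_head = zeros(1)

    # -- parameters --------------------------------------------------------

    def parameters(self) -> list[Tensor]:
        ps = [self.W_emb, self.b_emb]
        for blk in self.blocks:
            ps.extend(blk.values())
        ps.extend([self.W_head, self.b_head])
        return ps

    # -- forward pieces ----------------------------------------------------

    def _attention(self, q: Tensor, k: Tensor, v: Tensor) -> Tensor:
        scores = q.circ_corr_scores(k)  # (B, L), channel-averaged
        delays, _ = topk_delays(scores.data, self.cfg.c_factor, self.L)
        weights = scores.take_lags(delays).softmax(axis=-1)
        return v.delay_aggregate(delays, weights)

    def _decomp_residual(self, x: Tensor) -> Tensor:
        return x - x.moving_average(self.cfg.decomp_window)

    def _encoder_block(self, x: Tensor, blk: dict, rng) -> Tensor:
        p = self.cfg.dropout
        a = self._attention(x, x, x).gelu().dropout(p, rng)
        s1 = self._decomp_residual(x + a)
        b = ((s1 @ blk["Wc"]) + blk["bc"]).gelu().dropout(p, rng)
        s2 = self._decomp_residual(s1 + b)
        return s2.layer_norm() * blk["ln_g"] + blk["ln_b"]

    def forward(self, x: np.ndarray | EncodedInput, rng: np.random.Generator | None = None) -> Tensor:
        """Run the network on a (batch, channels, L) array.

        ``rng`` enables dropout (training mode); None means evaluation mode.
        Returns a graph-connected tensor of one prediction per sample.
        """
        if isinstance(x, EncodedInput):
            x = x.array
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[2] != self.L:
            raise ValueError(
                f"expected input (batch, {self.cfg.in_channels}, {self.L}), got {x.shape}"
            )
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} channels for "
                f"base_encoding={self.cfg.base_encoding!r}, use_kgm={self.cfg.use_kgm}, "
                f"got {x.shape[1]}"
            )
        h = Tensor(x.astype(self.dtype, copy=False)).conv1d(self.W_emb, self.b_emb) + Tensor(
            self.pe[None]
        )
        for blk in self.blocks:
            h = self._encoder_block(h, blk, rng)
        B = x.shape[0]
        out = h.reshape(B, self.L * self.cfg.d_model) @ self.W_head + self.b_head
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError("non-finite network output")
        return out.reshape(B)

    def predict(self, x: np.ndarray | EncodedInput) -> np.ndarray:
        """Evaluation-mode predictions as a plain numpy vector."""
        return self.forward(x, rng=None).data.copy()

    # -- checkpointing -----------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {"W_emb": self.W_emb.data, "b_emb": self.b_emb.data}
        for i, blk in enumerate(self.blocks):
            for name, t in blk.items():
                state[f"block{i}.{name}"] = t.data
        state["W_head"] = self.W_head.data
        state["b_head"] = self.b_head.data
        return state

    def save(self, path: str | Path) -> None:
        """Write parameters, config and positions to an .npz checkpoint."""
        meta = json.dumps(asdict(self.cfg))
        np.savez(
            path,
            __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
            __positions__=self.positions,
            **self.state_arrays(),
        )

    @classmethod
    def load(cls, path: str | Path) -> "GPformer":
        with np.load(path) as z:
            cfg = ModelConfig(**json.loads(bytes(z["__config__"]).decode()))
            positions = z["__positions__"]
            model = cls(cfg, n_markers=positions.size, positions=positions)
            for name, arr in model.state_arrays().items():
                target = z[name]
                if arr.shape != target.shape:  # pragma: no cover
                    raise ValueError(f"checkpoint shape mismatch for {name}")
            model.W_emb.data = z["W_emb"].copy()
            model.b_emb.data = z["b_emb"].copy()
            for i, blk in enumerate(model.blocks):
                for name in blk:
                    blk[name].data = z[f"block{i}.{name}"].copy()
            model.W_head.data = z["W_head"].copy()
            model.b_head.data = z["b_head"].copy()
        return model
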