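"""Selective multi-task recurrent network.

Architecture: a shared LSTM consumes the full 39-dimensional inputs; two
attention-based LSTM layers with *shared parameters* consume the shared
hidden states concatenated with the original features (the stability branch
sees only a feature subset — Hgb change, demographics, time difference and
observation indicators — realized by zero-masking the remaining columns so
the shared recurrent weights keep one input width).  Four 2-layer MLP heads
predict per timestep: stability (from branch 1), and normality, Hgb value and
selection probability (from branch 2).  Each head reads its branch's last
prefix hidden state concatenated with the prefix-attention context: the
hidden state carries the current memory, the attention context re-weights
long-range history.  Normality/stability/selection end in a sigmoid; the
value head passes through a softplus so predictions stay positive.

Predictions are causal: the prediction for timestep ``t`` attends only over
hidden states of timesteps ``0..t-1`` (feed-forward attention, a softmax over
the prefix), so the first draw of an encounter has no prediction and padded
timesteps receive zero attention weight.

Ablations (the benchmark variants): ``use_attention=False`` replaces the
attention context with the last prefix hidden state; ``use_selection=False``
removes the selection head; ``vanilla_lstm=True`` reduces the network to the
shared LSTM plus heads.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encounters import FEATURE_NAMES, N_FEATURES, STABILITY_SUBSET_COLS

DEFAULT_STABILITY_SUBSET = [FEATURE_NAMES[i] for i in STABILITY_SUBSET_COLS]


@dataclass
class ModelConfig:
    hidden_size: int = 64
    mlp_hidden: int = 32
    dropout: float = 0.1
    use_attention: bool = True
    use_selection: bool = True
    vanilla_lstm: bool = False
    feature_subset_stability: list = field(default_factory=lambda: list(DEFAULT_STABILITY_SUBSET))
    seed: int = 0

    def subset_cols(self) -> np.ndarray:
        return np.array([FEATURE_NAMES.index(n) for n in self.feature_subset_stability])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class PredictionBundle:
    """Per-timestep model outputs as plain arrays, shape (N, 30)."""
    p: np.ndarray           # selection probability in [0,1]
    normality: np.ndarray   # sigma(f_Y) in [0,1]
    stability: np.ndarray   # sigma(f_Z) in [0,1]
    value: np.ndarray       # f_V >= 0, g/dL


def select(p: np.ndarray, tau: float, observed: np.ndarray) -> np.ndarray:
    """Selection mask: 1 iff p_t > tau (strict) and the Hgb is observed."""
    return (np.asarray(p) > tau) & (np.asarray(observed) > 0)


# -------------------------------------------------------------------- layers

def _uniform(rng, shape, fan_in):
    s = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-s, s, size=shape), requires_grad=True)


class LSTMLayer:
    """Single-layer LSTM; gate order (input, forget, cell, output)."""

    def __init__(self, in_dim: int, hidden: int, rng):
        self.in_dim, self.hidden = in_dim, hidden
        self.W = _uniform(rng, (in_dim + hidden, 4 * hidden), in_dim + hidden)
        b = np.zeros(4 * hidden)
        b[hidden: 2 * hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def params(self, prefix):
        return {f"{prefix}.W": self.W, f"{prefix}.b": self.b}

    def __call__(self, X: Tensor) -> Tensor:
        """X: (N, T, D) -> hidden states (N, T, H)."""
        N, T, _ = X.shape
        H = self.hidden
        h = Tensor(np.zeros((N, H)))
        c = Tensor(np.zeros((N, H)))
        outs = []
        for t in range(T):
            xt = X[:, t, :]
            gates = ad.concat([xt, h], axis=-1) @ self.W + self.b
            i = ad.sigmoid(gates[:, 0:H])
            f = ad.sigmoid(gates[:, H:2 * H])
            g = ad.tanh(gates[:, 2 * H:3 * H])
            o = ad.sigmoid(gates[:, 3 * H:4 * H])
            c = f * c + i * g
            h = o * ad.tanh(c)
            outs.append(h)
        return ad.stack(outs, axis=1)


class MLPHead:
    """Two fully-connected layers with a ReLU in between, scalar output."""

    def __init__(self, in_dim: int, hidden: int, rng):
        self.W1 = _uniform(rng, (in_dim, hidden), in_dim)
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.W2 = _uniform(rng, (hidden, 1), hidden)
        self.b2 = Tensor(np.zeros(1), requires_grad=True)

    def params(self, prefix):
        return {f"{prefix}.W1": self.W1, f"{prefix}.b1": self.b1,
                f"{prefix}.W2": self.W2, f"{prefix}.b2": self.b2}

    def __call__(self, X: Tensor) -> Tensor:
        """X: (..., in_dim) -> logits (...,) with the trailing axis squeezed."""
        h = ad.relu(X @ self.W1 + self.b1)
        out = h @ self.W2 + self.b2
        return out.reshape(*out.shape[:-1])


class SelectiveNet:
    """The full selective prediction network (see module docstring)."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        H = cfg.hidden_size
        self.shared = LSTMLayer(N_FEATURES, H, rng)
        if not cfg.vanilla_lstm:
            # one attention-LSTM instance serves both branches => parameters
            # are shared by construction
            self.attn_lstm = LSTMLayer(H + N_FEATURES, H, rng)
            self.score_w = _uniform(rng, (H, 1), H)
            self.score_b = Tensor(np.zeros(1), requires_grad=True)
        # heads read the branch's last prefix hidden state, concatenated
        # with the prefix-attention context when attention is on
        head_in = H if cfg.vanilla_lstm or not cfg.use_attention else 2 * H
        head_rng = rng
        self.head_z = MLPHead(head_in, cfg.mlp_hidden, head_rng)
        self.head_y = MLPHead(head_in, cfg.mlp_hidden, head_rng)
        self.head_v = MLPHead(head_in, cfg.mlp_hidden, head_rng)
        if cfg.use_selection and not cfg.vanilla_lstm:
            self.head_p = MLPHead(head_in, cfg.mlp_hidden, head_rng)
        else:
            self.head_p = None
        self._subset_mask = np.zeros(N_FEATURES)
        self._subset_mask[cfg.subset_cols()] = 1.0

    # ------------------------------------------------------------ parameters
    def parameters(self) -> dict[str, Tensor]:
        out = dict(self.shared.params("shared"))
        if not self.config.vanilla_lstm:
            out.update(self.attn_lstm.params("attn"))
            out["score.w"] = self.score_w
            out["score.b"] = self.score_b
        out.update(self.head_z.params("head_z"))
        out.update(self.head_y.params("head_y"))
        out.update(self.head_v.params("head_v"))
        if self.head_p is not None:
            out.update(self.head_p.params("head_p"))
        return out

    # --------------------------------------------------------------- helpers
    def _scores(self, Hseq: Tensor) -> Tensor:
        """Scoring map: an unbounded scalar e_t = w·h_t + b per timestep.

        Bounded scores (e.g. a tanh) cap the attention contrast and force the
        context towards a prefix average, diluting the most recent draw and
        with it the achievable prediction confidence; the affine map lets the
        softmax peak as sharply as the data warrants.
        """
        e = Hseq @ self.score_w + self.score_b
        return e.reshape(*e.shape[:-1])  # (N, T)

    @staticmethod
    def _last_prefix(Hseq: Tensor, seq_len: np.ndarray) -> Tensor:
        """Row t holds the hidden state of the last prefix timestep (t-1,
        clipped to the sequence length); row 0 is zero (empty prefix)."""
        N, T, H = Hseq.shape
        sel = np.zeros((N, T, T))
        ii, tt = np.meshgrid(np.arange(N), np.arange(1, T), indexing="ij")
        kk = np.minimum(tt, seq_len[:, None]) - 1
        ok = kk >= 0
        sel[ii[ok], tt[ok], kk[ok]] = 1.0
        return Tensor(sel) @ Hseq

    def _prefix_context(self, Hseq: Tensor, e: Tensor, seq_len: np.ndarray) -> Tensor:
        """Causal attention contexts: row t holds sum_k a_k h_k over k < t.

        Attention weights are a softmax of the scores over the strict prefix,
        with padded timesteps masked to weight zero; the t=0 row (empty
        prefix) yields a zero context.
        """
        N, T, H = Hseq.shape
        tt = np.arange(T)
        causal = (tt[None, :] < tt[:, None]).astype(float)          # (T, T)
        valid_src = (tt[None, :] < seq_len[:, None]).astype(float)  # (N, T)
        mask = causal[None, :, :] * valid_src[:, None, :]           # (N, T_tgt, T_src)
        # shift by the (constant) max so exp() stays in range; subtracting a
        # constant leaves the softmax and its gradient unchanged
        shift = float(np.max(e.data)) if e.data.size else 0.0
        w = ad.exp(e - shift).reshape(N, 1, T) * Tensor(mask)
        denom = w.sum(axis=2, keepdims=True)
        has_any = (mask.sum(axis=2, keepdims=True) > 0).astype(float)
        a = w / (denom + Tensor(1.0 - has_any))
        return a @ Hseq

    def feed_forward_attention(self, hidden_seq: Tensor | np.ndarray, prefix_end: int) -> Tensor:
        """Context vector over timesteps 0..prefix_end (inclusive) of (T, H) states."""
        Hseq = hidden_seq if isinstance(hidden_seq, Tensor) else Tensor(hidden_seq)
        T = Hseq.shape[0]
        if prefix_end < 0 or prefix_end >= T:
            raise ValueError(f"prefix_end {prefix_end} outside sequence of length {T}")
        prefix = Hseq[0:prefix_end + 1, :]
        e = self._scores(prefix.reshape(1, prefix_end + 1, -1)).reshape(prefix_end + 1)
        w = ad.exp(e - float(np.max(e.data)))
        a = w / w.sum()
        return (a.reshape(prefix_end + 1, 1) * prefix).sum(axis=0)

    def _dropout(self, x: Tensor, rng) -> Tensor:
        q = self.config.dropout
        if rng is None or q <= 0.0:
            return x
        keep = (rng.random(x.shape) >= q) / (1.0 - q)
        return x * Tensor(keep)

    # ---------------------------------------------------------------- forward
    def forward(self, X: np.ndarray, seq_len: np.ndarray, train_rng=None) -> dict[str, Tensor]:
        """Run the network on standardized features.

        X: (N, 30, 39) float array; seq_len: (N,) non-padded lengths.
        Returns per-timestep Tensors: probabilities 'y', 'z', 'p' (p is None
        under the no-selection/vanilla ablations) and positive values 'v'.
        Row t of every output is the prediction *for* timestep t, computed
        from draws 0..t-1 only.
        """
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[2] != N_FEATURES:
            raise ValueError(f"expected features of width {N_FEATURES}, got {X.shape}")
        Xt = Tensor(X)
        Hs = self.shared(Xt)
        cfg = self.config
        if cfg.vanilla_lstm:
            ctx = self._dropout(self._last_prefix(Hs, seq_len), train_rng)
            return {"y": ad.sigmoid(self.head_y(ctx)),
                    "z": ad.sigmoid(self.head_z(ctx)),
                    "v": ad.softplus(self.head_v(ctx)),
                    "p": None}
        Xsub = Tensor(X * self._subset_mask)
        Ha_stab = self.attn_lstm(ad.concat([Hs, Xsub], axis=-1))
        Ha_full = self.attn_lstm(ad.concat([Hs, Xt], axis=-1))
        last_stab = self._last_prefix(Ha_stab, seq_len)
        last_full = self._last_prefix(Ha_full, seq_len)
        if cfg.use_attention:
            ctx_stab = ad.concat(
                [last_stab, self._prefix_context(Ha_stab, self._scores(Ha_stab), seq_len)],
                axis=-1)
            ctx_full = ad.concat(
                [last_full, self._prefix_context(Ha_full, self._scores(Ha_full), seq_len)],
                axis=-1)
        else:
            ctx_stab, ctx_full = last_stab, last_full
        ctx_stab = self._dropout(ctx_stab, train_rng)
        ctx_full = self._dropout(ctx_full, train_rng)
        out = {"z": ad.sigmoid(self.head_z(ctx_stab)),
               "y": ad.sigmoid(self.head_y(ctx_full)),
               "v": ad.softplus(self.head_v(ctx_full)),
               "p": ad.sigmoid(self.head_p(ctx_full)) if cfg.use_selection else None}
        return out

    def predict(self, X: np.ndarray, seq_len: np.ndarray) -> PredictionBundle:
        out = self.forward(X, seq_len)
        N, T = X.shape[0], X.shape[1]
        p = out["p"].data if out["p"] is not None else np.ones((N, T))
        return PredictionBundle(p=p.copy(), normality=out["y"].data.copy(),
                                stability=out["z"].data.copy(), value=out["v"].data.copy())

    # ------------------------------------------------------------ persistence
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        for k, v in params.items():
            v.data = np.asarray(state[k], dtype=np.float64).copy()

    def save(self, path) -> None:
        buf = {k: v for k, v in self.state_dict().items()}
        buf["_config_json"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8)
        np.savez(path, **buf)

    @classmethod
    def load(cls, path) -> "SelectiveNet":
        with np.load(path) as z:
            cfg = ModelConfig.from_dict(json.loads(bytes(z["_config_json"]).decode()))
            model = cls(cfg)
            model.load_state_dict({k: z[k] for k in z.files if k != "_config_json"})
        return model
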