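"""PatchCrossFormer: patch/cross-attention forecaster, plus recurrent baselines.

The network forecasts the three indoor targets (temperature, humidity, CO2)
H steps ahead from N past steps of all six channels. Environmental target
channels are embedded on the time axis as k = N/L non-overlapping patch
tokens plus one whole-sequence global token; auxiliary channels (wind
speed, outdoor temperature/humidity) are embedded on the channel axis, one
token each. Each encoder layer runs a Patch-Global Aggregator (additive
attention conditioned on the recurrent state) feeding a GRU over the k+1
tokens, fuses auxiliary information through scaled-dot-product
cross-attention (queries = temporal encodings, keys/values = auxiliary
tokens) with residual + layer-norm, and finishes with a position-wise
feed-forward block. Three parallel linear heads, one per target, map the
flattened (k+1) x d encoding of that target's channel to H values.

All ablation switches (`use_patch_encoding`, `use_aggregator`,
`use_cross_attention`) remove their module's parameters entirely, so each
ablated variant is strictly smaller than the full model.

The module-level functions (`patchify`, `positional_encoding`,
`aggregate_step`, `gru_cell`, `cross_attention`) are plain-NumPy reference
forms of each building block; the model itself runs on the package's
autodiff tensors so the two routes can be checked against each other.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np

from ._autodiff import Tensor, concat, softmax, layer_norm


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class ModelConfig:
    N: int = 48            # input sequence length (10-min steps)
    H: int = 12            # forecast horizon
    L: int = 12            # patch length; falls back to N when N < L
    d: int = 256           # feature dimension
    n_layers: int = 3      # encoder layers
    n_env: int = 3         # environmental (target) channels
    n_aux: int = 3         # auxiliary channels
    n_heads: int = 1       # cross-attention heads
    ffn_hidden: int = 512  # feed-forward width
    use_patch_encoding: bool = True
    use_aggregator: bool = True
    use_cross_attention: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.H < 1:
            raise ValueError("H must be >= 1")
        if self.d % 2 != 0:
            raise ValueError("feature dimension d must be even")
        if self.d % self.n_heads != 0:
            raise ValueError("n_heads must divide d")
        _ = self.effective_L  # validate divisibility

    @property
    def effective_L(self) -> int:
        L = self.N if self.N < self.L else self.L
        if self.N % L != 0:
            divisors = [v for v in range(1, self.N + 1) if self.N % v == 0]
            raise ValueError(
                f"patch length {L} does not divide N={self.N}; valid lengths: {divisors}"
            )
        return L

    @property
    def k(self) -> int:
        """Number of patches per environmental channel."""
        return self.N // self.effective_L

    @property
    def n_tokens(self) -> int:
        """Token-set size per channel: k patches + 1 global, or 1 when
        patch encoding is ablated."""
        return self.k + 1 if self.use_patch_encoding else 1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


SMOKE_PROFILE = dict(d=32, n_layers=1, ffn_hidden=64)


# --------------------------------------------------------------------------
# reference building blocks (plain NumPy)
# --------------------------------------------------------------------------

def patchify(sequence: np.ndarray, L: int) -> np.ndarray:
    """Split a length-N series into k = N/L contiguous patches, shape (k, L).

    When N < L the patch length falls back to N (one patch). Concatenating
    the patches restores the input exactly.
    """
    x = np.asarray(sequence)
    N = x.shape[-1]
    if N < L:
        L = N
    if N % L != 0:
        divisors = [v for v in range(1, N + 1) if N % v == 0]
        raise ValueError(f"L={L} does not divide N={N}; valid lengths: {divisors}")
    return x.reshape(*x.shape[:-1], N // L, L)


def positional_encoding(pos: int | np.ndarray, d: int) -> np.ndarray:
    """Sinusoidal positional encoding: p[2i] = sin(pos/10000^(2i/d)),
    p[2i+1] = cos(pos/10000^(2i/d)). No trainable parameters."""
    if d % 2 != 0:
        raise ValueError("d must be even")
    pos = np.asarray(pos, dtype=float)
    i = np.arange(d // 2)
    angle = pos[..., None] / (10000.0 ** (2.0 * i / d))
    out = np.empty(pos.shape + (d,))
    out[..., 0::2] = np.sin(angle)
    out[..., 1::2] = np.cos(angle)
    return out


def aggregate_step(tokens: np.ndarray, h_prev: np.ndarray,
                   w_e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One Patch-Global Aggregator step.

    e_j = tanh(w_e . [h_prev; p_j]); alpha = softmax_j(e); readout
    p~ = sum_j alpha_j p_j. Returns (p~, alpha)."""
    tokens = np.asarray(tokens, dtype=float)
    T, d = tokens.shape
    cat = np.concatenate([np.broadcast_to(h_prev, (T, d)), tokens], axis=1)
    e = np.tanh(cat @ w_e)
    e = e - e.max()
    alpha = np.exp(e) / np.exp(e).sum()
    return alpha @ tokens, alpha


def gru_cell(x: np.ndarray, h_prev: np.ndarray, params: dict) -> np.ndarray:
    """One GRU step on [h_prev; x] concatenation:

    z = sigma(Wz[h;x]+bz); r = sigma(Wr[h;x]+br);
    h~ = tanh(Wh[r*h; x]+bh); h' = (1-z)*h + z*h~.
    """
    cat = np.concatenate([h_prev, x])
    z = _sigmoid(cat @ params["Wz"] + params["bz"])
    r = _sigmoid(cat @ params["Wr"] + params["br"])
    cat_r = np.concatenate([r * h_prev, x])
    h_cand = np.tanh(cat_r @ params["Wh"] + params["bh"])
    return (1.0 - z) * h_prev + z * h_cand


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def cross_attention(queries: np.ndarray, keys_values: np.ndarray, params: dict,
                    n_heads: int = 1):
    """Scaled dot-product cross-attention with residual + layer-norm.

    Returns (out, weights, pre_residual): `weights` has shape (heads, m, n)
    and rows summing to 1; `pre_residual` is the attention output before
    the residual connection and normalization.
    """
    Q = queries @ params["Wq"]
    K = keys_values @ params["Wk"]
    V = keys_values @ params["Wv"]
    m, d = Q.shape
    n = K.shape[0]
    dk = d // n_heads
    Qh = Q.reshape(m, n_heads, dk).transpose(1, 0, 2)
    Kh = K.reshape(n, n_heads, dk).transpose(1, 0, 2)
    Vh = V.reshape(n, n_heads, dk).transpose(1, 0, 2)
    scores = Qh @ Kh.transpose(0, 2, 1) / np.sqrt(dk)
    scores = scores - scores.max(axis=-1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=-1, keepdims=True)
    attn = (w @ Vh).transpose(1, 0, 2).reshape(m, d)
    pre = attn @ params["Wo"]
    out = _ln_np(queries + pre, params["ln_g"], params["ln_b"])
    return out, w, pre


def _ln_np(x, g, b, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * g + b


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------

class PatchCrossFormer:
    """Patch- and cross-attention forecaster for the three indoor targets."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._rng = np.random.default_rng(config.seed)
        self._build()

    # ---- parameter construction ---------------------------------------
    def _uniform(self, shape, fan_in) -> Tensor:
        bound = 1.0 / np.sqrt(fan_in)
        return Tensor(self._rng.uniform(-bound, bound, size=shape), requires_grad=True)

    def _zeros(self, shape) -> Tensor:
        return Tensor(np.zeros(shape), requires_grad=True)

    def _ones(self, shape) -> Tensor:
        return Tensor(np.ones(shape), requires_grad=True)

    def _build(self):
        cfg = self.config
        d, L, N = cfg.d, cfg.effective_L, cfg.N
        p = self.params
        if cfg.use_patch_encoding:
            p["embed.patch.W"] = self._uniform((L, d), L)
            p["embed.patch.b"] = self._zeros(d)
        p["embed.global.W"] = self._uniform((N, d), N)
        p["embed.global.b"] = self._zeros(d)
        for c in range(cfg.n_aux):
            p[f"embed.aux{c}.W"] = self._uniform((N, d), N)
            p[f"embed.aux{c}.b"] = self._zeros(d)
        for l in range(cfg.n_layers):
            if cfg.use_aggregator:
                p[f"enc{l}.agg.w"] = self._uniform((2 * d,), 2 * d)
            for gate in ("Wz", "Wr", "Wh"):
                p[f"enc{l}.gru.{gate}"] = self._uniform((2 * d, d), 2 * d)
            for gate in ("bz", "br", "bh"):
                p[f"enc{l}.gru.{gate}"] = self._zeros(d)
            if cfg.use_cross_attention:
                for w in ("Wq", "Wk", "Wv", "Wo"):
                    p[f"enc{l}.attn.{w}"] = self._uniform((d, d), d)
            p[f"enc{l}.ln1.g"] = self._ones(d)
            p[f"enc{l}.ln1.b"] = self._zeros(d)
            p[f"enc{l}.ffn.W1"] = self._uniform((d, cfg.ffn_hidden), d)
            p[f"enc{l}.ffn.b1"] = self._zeros(cfg.ffn_hidden)
            p[f"enc{l}.ffn.W2"] = self._uniform((cfg.ffn_hidden, d), cfg.ffn_hidden)
            p[f"enc{l}.ffn.b2"] = self._zeros(d)
            p[f"enc{l}.ln2.g"] = self._ones(d)
            p[f"enc{l}.ln2.b"] = self._zeros(d)
        flat = cfg.n_tokens * d
        for i in range(cfg.n_env):
            p[f"head{i}.W"] = self._uniform((flat, cfg.H), flat)
            p[f"head{i}.b"] = self._zeros(cfg.H)

    # ---- bookkeeping ----------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def num_params(self) -> int:
        return sum(t.data.size for t in self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        if set(state) != set(self.params):
            missing = set(self.params) ^ set(state)
            raise ValueError(f"parameter set mismatch: {sorted(missing)}")
        for k, t in self.params.items():
            if t.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            t.data = state[k].copy()

    # ---- embedding ------------------------------------------------------
    def embed_environmental(self, x: np.ndarray) -> np.ndarray:
        """Token set (n_tokens, d) for one environmental channel series."""
        t = self._embed_env(Tensor(np.asarray(x, dtype=float)[None, None, :]))
        return t.data[0, 0]

    def embed_auxiliary(self, S: np.ndarray) -> np.ndarray:
        """Tokens (n_aux, d) for the auxiliary channel block (n_aux, N)."""
        S = np.asarray(S, dtype=float)
        if S.shape[0] != self.config.n_aux:
            raise ValueError(
                f"expected {self.config.n_aux} auxiliary channels, got {S.shape[0]}"
            )
        t = self._embed_aux(Tensor(S.T[None, :, :]))
        return t.data[0]

    def _embed_env(self, env: Tensor) -> Tensor:
        """(B, n_env, N) -> (B, n_env, n_tokens, d); projections shared
        across channels; PE added at token positions 1..n_tokens."""
        cfg = self.config
        B, n_env, N = env.shape
        L, d, k = cfg.effective_L, cfg.d, cfg.k
        p = self.params
        g = env.reshape(B * n_env, N) @ p["embed.global.W"] + p["embed.global.b"]
        if cfg.use_patch_encoding:
            patches = env.reshape(B * n_env, k, L) @ p["embed.patch.W"] + p["embed.patch.b"]
            tokens = concat([patches, g.reshape(B * n_env, 1, d)], axis=1)
        else:
            tokens = g.reshape(B * n_env, 1, d)
        pe = positional_encoding(np.arange(1, cfg.n_tokens + 1), d)
        return (tokens + Tensor(pe)).reshape(B, n_env, cfg.n_tokens, d)

    def _embed_aux(self, aux: Tensor) -> Tensor:
        """(B, N, n_aux) -> (B, n_aux, d); one projection per channel,
        channel-index PE added."""
        cfg = self.config
        B = aux.shape[0]
        toks = []
        for c in range(cfg.n_aux):
            t = aux[:, :, c] @ self.params[f"embed.aux{c}.W"] + self.params[f"embed.aux{c}.b"]
            pe = positional_encoding(np.array(c + 1), cfg.d)
            toks.append((t + Tensor(pe)).reshape(B, 1, cfg.d))
        return concat(toks, axis=1)

    # ---- encoder --------------------------------------------------------
    def _encode_tokens(self, tokens: Tensor, layer: int) -> tuple[Tensor, list[np.ndarray]]:
        """Aggregator + GRU over a (Bc, T, d) token set -> (Bc, T, d) hidden
        states; also returns the per-step attention weights."""
        cfg = self.config
        Bc, T, d = tokens.shape
        p = self.params
        h = Tensor(np.zeros((Bc, d)))
        hs, alphas = [], []
        for t in range(T):
            if cfg.use_aggregator:
                h_rep = h.reshape(Bc, 1, d) + Tensor(np.zeros((Bc, T, d)))
                e = concat([h_rep, tokens], axis=2) @ p[f"enc{layer}.agg.w"]
                alpha = softmax(e.tanh(), axis=1)  # (Bc, T)
                p_t = (alpha.reshape(Bc, T, 1) * tokens).sum(axis=1)
                alphas.append(alpha.data)
            else:
                p_t = tokens[:, t, :]
            h = self._gru(p_t, h, layer)
            hs.append(h.reshape(Bc, 1, d))
        return concat(hs, axis=1), alphas

    def _gru(self, x: Tensor, h: Tensor, layer: int) -> Tensor:
        p = self.params
        cat = concat([h, x], axis=-1)
        z = (cat @ p[f"enc{layer}.gru.Wz"] + p[f"enc{layer}.gru.bz"]).sigmoid()
        r = (cat @ p[f"enc{layer}.gru.Wr"] + p[f"enc{layer}.gru.br"]).sigmoid()
        cat_r = concat([r * h, x], axis=-1)
        h_cand = (cat_r @ p[f"enc{layer}.gru.Wh"] + p[f"enc{layer}.gru.bh"]).tanh()
        return (1.0 - z) * h + z * h_cand

    def encode_channel(self, tokens: np.ndarray, layer: int = 0) -> np.ndarray:
        """Hidden-state sequence (T, d) for one channel's token set."""
        hs, _ = self._encode_tokens(Tensor(np.asarray(tokens, dtype=float)[None]), layer)
        return hs.data[0]

    def _cross_attend(self, q: Tensor, kv: Tensor, layer: int) -> Tensor:
        """(Bc, T, d) queries vs (Bc, n_kv, d) keys/values; residual + LN.
        With cross-attention ablated, layer-norm of the queries alone."""
        cfg = self.config
        p = self.params
        if not cfg.use_cross_attention:
            return layer_norm(q, p[f"enc{layer}.ln1.g"], p[f"enc{layer}.ln1.b"])
        Bc, T, d = q.shape
        n_kv = kv.shape[1]
        h_, dk = cfg.n_heads, d // cfg.n_heads
        Q = (q @ p[f"enc{layer}.attn.Wq"]).reshape(Bc, T, h_, dk).transpose(0, 2, 1, 3)
        K = (kv @ p[f"enc{layer}.attn.Wk"]).reshape(Bc, n_kv, h_, dk).transpose(0, 2, 1, 3)
        V = (kv @ p[f"enc{layer}.attn.Wv"]).reshape(Bc, n_kv, h_, dk).transpose(0, 2, 1, 3)
        scores = Q @ K.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(dk))
        w = softmax(scores, axis=-1)
        attn = (w @ V).transpose(0, 2, 1, 3).reshape(Bc, T, d)
        out = attn @ p[f"enc{layer}.attn.Wo"]
        return layer_norm(q + out, p[f"enc{layer}.ln1.g"], p[f"enc{layer}.ln1.b"])

    def _ffn(self, x: Tensor, layer: int) -> Tensor:
        p = self.params
        h = (x @ p[f"enc{layer}.ffn.W1"] + p[f"enc{layer}.ffn.b1"]).relu()
        out = h @ p[f"enc{layer}.ffn.W2"] + p[f"enc{layer}.ffn.b2"]
        return layer_norm(x + out, p[f"enc{layer}.ln2.g"], p[f"enc{layer}.ln2.b"])

    # ---- forward --------------------------------------------------------
    def forward_tensor(self, env: np.ndarray, aux: np.ndarray) -> Tensor:
        """Differentiable forward pass: (B, N, n_env) + (B, N, n_aux) ->
        (B, H, n_env) on the normalized scale."""
        cfg = self.config
        env = np.asarray(env, dtype=float)
        aux = np.asarray(aux, dtype=float)
        if env.ndim != 3 or env.shape[1:] != (cfg.N, cfg.n_env):
            raise ValueError(
                f"env must have shape (B, {cfg.N}, {cfg.n_env}), got {env.shape}"
            )
        if aux.shape != (env.shape[0], cfg.N, cfg.n_aux):
            raise ValueError(
                f"aux must have shape ({env.shape[0]}, {cfg.N}, {cfg.n_aux}), got {aux.shape}"
            )
        if not (np.isfinite(env).all() and np.isfinite(aux).all()):
            raise ValueError("non-finite values in model input")
        B = env.shape[0]
        T, d = cfg.n_tokens, cfg.d

        tokens = self._embed_env(Tensor(env).transpose(0, 2, 1))  # (B, n_env, T, d)
        tokens = tokens.reshape(B * cfg.n_env, T, d)
        aux_tok = self._embed_aux(Tensor(aux))  # (B, n_aux, d)
        # repeat auxiliary tokens for each environmental channel in the fold
        kv = concat([aux_tok.reshape(B, 1, cfg.n_aux, d)] * cfg.n_env, axis=1)
        kv = kv.reshape(B * cfg.n_env, cfg.n_aux, d)

        x = tokens
        for l in range(cfg.n_layers):
            hs, _ = self._encode_tokens(x, l)
            fused = self._cross_attend(hs, kv, l)
            x = self._ffn(fused, l)

        x = x.reshape(B, cfg.n_env, T * d)
        outs = []
        for i in range(cfg.n_env):
            y = x[:, i, :] @ self.params[f"head{i}.W"] + self.params[f"head{i}.b"]
            outs.append(y.reshape(B, cfg.H, 1))
        return concat(outs, axis=2)

    def forward(self, env: np.ndarray, aux: np.ndarray) -> np.ndarray:
        return self.forward_tensor(env, aux).data

    def predict_windows(self, inputs: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Forward over (B, N, 6) windows laid out [env | aux] on the
        channel axis, in evaluation batches."""
        cfg = self.config
        outs = []
        for i in range(0, len(inputs), batch_size):
            chunk = inputs[i:i + batch_size]
            outs.append(self.forward(chunk[:, :, :cfg.n_env], chunk[:, :, cfg.n_env:]))
        return np.concatenate(outs, axis=0)


# --------------------------------------------------------------------------
# recurrent baselines
# --------------------------------------------------------------------------

class RecurrentBaseline:
    """RNN/GRU/LSTM baseline: 3 stacked layers, 256 hidden units, tanh,
    all six channels concatenated per step, linear head to H x 3."""

    KINDS = ("rnn", "gru", "lstm")

    def __init__(self, kind: str, config: ModelConfig, hidden: int = 256,
                 n_layers: int = 3):
        if kind not in self.KINDS:
            raise ValueError(f"unknown baseline kind {kind!r}; valid: {self.KINDS}")
        self.kind = kind
        self.config = config
        self.hidden = hidden
        self.n_layers = n_layers
        self.params: dict[str, Tensor] = {}
        self._rng = np.random.default_rng(config.seed)
        self._build()

    def _uniform(self, shape, fan_in) -> Tensor:
        bound = 1.0 / np.sqrt(fan_in)
        return Tensor(self._rng.uniform(-bound, bound, size=shape), requires_grad=True)

    def _build(self):
        h = self.hidden
        gates = {"rnn": ("W",), "gru": ("Wz", "Wr", "Wh"),
                 "lstm": ("Wi", "Wf", "Wo", "Wg")}[self.kind]
        n_in = self.config.n_env + self.config.n_aux
        for l in range(self.n_layers):
            in_l = n_in if l == 0 else h
            for g in gates:
                self.params[f"l{l}.{g}"] = self._uniform((h + in_l, h), h + in_l)
                self.params[f"l{l}.b{g[1:] or 'w'}"] = Tensor(np.zeros(h), requires_grad=True)
        out_dim = self.config.H * self.config.n_env
        self.params["head.W"] = self._uniform((h, out_dim), h)
        self.params["head.b"] = Tensor(np.zeros(out_dim), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def num_params(self) -> int:
        return sum(t.data.size for t in self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        if set(state) != set(self.params):
            raise ValueError("parameter set mismatch")
        for k, t in self.params.items():
            t.data = state[k].copy()

    def _step(self, x: Tensor, h: Tensor, c: Tensor | None, l: int):
        p = self.params
        cat = concat([h, x], axis=-1)
        if self.kind == "rnn":
            return (cat @ p[f"l{l}.W"] + p[f"l{l}.bw"]).tanh(), None
        if self.kind == "gru":
            z = (cat @ p[f"l{l}.Wz"] + p[f"l{l}.bz"]).sigmoid()
            r = (cat @ p[f"l{l}.Wr"] + p[f"l{l}.br"]).sigmoid()
            cat_r = concat([r * h, x], axis=-1)
            h_cand = (cat_r @ p[f"l{l}.Wh"] + p[f"l{l}.bh"]).tanh()
            return (1.0 - z) * h + z * h_cand, None
        i = (cat @ p[f"l{l}.Wi"] + p[f"l{l}.bi"]).sigmoid()
        f = (cat @ p[f"l{l}.Wf"] + p[f"l{l}.bf"]).sigmoid()
        o = (cat @ p[f"l{l}.Wo"] + p[f"l{l}.bo"]).sigmoid()
        g = (cat @ p[f"l{l}.Wg"] + p[f"l{l}.bg"]).tanh()
        c_new = f * c + i * g
        return o * c_new.tanh(), c_new

    def forward_tensor(self, env: np.ndarray, aux: np.ndarray) -> Tensor:
        cfg = self.config
        x = np.concatenate([np.asarray(env, float), np.asarray(aux, float)], axis=2)
        B, N, _ = x.shape
        if N != cfg.N:
            raise ValueError(f"expected N={cfg.N} steps, got {N}")
        seq: list[Tensor] = [Tensor(x[:, t, :]) for t in range(N)]
        for l in range(self.n_layers):
            h = Tensor(np.zeros((B, self.hidden)))
            c = Tensor(np.zeros((B, self.hidden))) if self.kind == "lstm" else None
            out_seq = []
            for t in range(N):
                h, c = self._step(seq[t], h, c, l)
                out_seq.append(h)
            seq = out_seq
        y = seq[-1] @ self.params["head.W"] + self.params["head.b"]
        return y.reshape(B, cfg.H, cfg.n_env)

    def forward(self, env: np.ndarray, aux: np.ndarray) -> np.ndarray:
        return self.forward_tensor(env, aux).data

    def predict_windows(self, inputs: np.ndarray, batch_size: int = 256) -> np.ndarray:
        cfg = self.config
        outs = []
        for i in range(0, len(inputs), batch_size):
            chunk = inputs[i:i + batch_size]
            outs.append(self.forward(chunk[:, :, :cfg.n_env], chunk[:, :, cfg.n_env:]))
        return np.concatenate(outs, axis=0)


def build_baseline(kind: str, config: ModelConfig, hidden: int = 256,
                   n_layers: int = 3) -> RecurrentBaseline:
    """Recurrent baseline with the same forward contract as the main model."""
    return RecurrentBaseline(kind, config, hidden=hidden, n_layers=n_layers)
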