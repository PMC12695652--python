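"""Transformer encoder over token sequences, implemented in NumPy.

The model is a pre-norm encoder: token embeddings plus learnable positional
embeddings, then a stack of blocks, each a PAD-masked multihead
self-attention followed by a GELU feed-forward network, both applied to the
layer-normalized input and added back onto the residual stream; a final
layer normalization feeds an (optionally tied) linear decoder over the full
vocabulary for masked-token prediction. The pre-norm layout keeps the token
and positional embeddings additively present in the residual stream, which
stabilizes training and preserves token identity in mean-pooled cell
embeddings.

Initialization: linear weights are Xavier-uniform with zero biases;
embedding tables are drawn N(0, 1/sqrt(d_model)) — fan-based scaling is not
meaningful for lookup tables.

PAD handling: PAD key positions are masked to -inf before the attention
softmax, so no token ever attends to PAD and attention columns at PAD
positions are exactly zero; every row is a probability vector over the
non-PAD keys.

Both the forward pass and the analytic backward pass are written out
explicitly; gradients are verified against finite differences in the test
suite.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.special import erf

__all__ = ["EncoderConfig", "EncoderModel", "build_model"]

_LN_EPS = 1e-5
_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters.

    Defaults follow the full-scale setting (12 blocks, 16 heads, D=512,
    FFN 1024, sequences of 1,500 tokens, no dropout); tests and desk-scale
    runs shrink them.
    """

    vocab_size: int
    n_layers: int = 12
    n_heads: int = 16
    d_model: int = 512
    d_ffn: int = 1024
    max_len: int = 1500
    dropout: float = 0.0
    tie_decoder: bool = False
    pad_id: int = 0
    dtype: str = "float32"  # single-precision deterministic mode is the default
    residual_scale: float = 0.1  # init scale of the residual output projections

    def __post_init__(self) -> None:
        for name in ("vocab_size", "n_layers", "n_heads", "d_model", "d_ffn", "max_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model={self.d_model} must be divisible by n_heads={self.n_heads}"
            )
        if self.dropout != 0.0:
            raise ValueError("only dropout=0.0 is supported in the deterministic NumPy path")


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * np.exp(-0.5 * x * x) * _INV_SQRT_2PI


def _layer_norm(x: np.ndarray, g: np.ndarray, b: np.ndarray):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv)


def _layer_norm_backward(dy: np.ndarray, g: np.ndarray, cache):
    xhat, inv = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    return dx, dg, db


class EncoderModel:
    """NumPy transformer encoder with explicit forward/backward passes."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        p: dict[str, np.ndarray] = {}
        emb_std = 1.0 / math.sqrt(c.d_model)
        p["tok_emb"] = rng.normal(0.0, emb_std, size=(c.vocab_size, c.d_model))
        p["pos_emb"] = rng.normal(0.0, emb_std, size=(c.max_len, c.d_model))
        for i in range(c.n_layers):
            for w in ("Wq", "Wk", "Wv", "Wo"):
                p[f"l{i}.{w}"] = _xavier(rng, c.d_model, c.d_model)
                p[f"l{i}.{w[0].lower()}{w[1].lower()}_b"] = np.zeros(c.d_model)
            # residual output projections start small so the embedding
            # stream dominates early training
            p[f"l{i}.Wo"] *= c.residual_scale
            p[f"l{i}.ln1_g"] = np.ones(c.d_model)
            p[f"l{i}.ln1_b"] = np.zeros(c.d_model)
            p[f"l{i}.W1"] = _xavier(rng, c.d_model, c.d_ffn)
            p[f"l{i}.b1"] = np.zeros(c.d_ffn)
            p[f"l{i}.W2"] = _xavier(rng, c.d_ffn, c.d_model) * c.residual_scale
            p[f"l{i}.b2"] = np.zeros(c.d_model)
            p[f"l{i}.ln2_g"] = np.ones(c.d_model)
            p[f"l{i}.ln2_b"] = np.zeros(c.d_model)
        p["lnf_g"] = np.ones(c.d_model)
        p["lnf_b"] = np.zeros(c.d_model)
        if not c.tie_decoder:
            p["dec_W"] = _xavier(rng, c.d_model, c.vocab_size)
        p["dec_b"] = np.zeros(c.vocab_size)
        dt = np.dtype(c.dtype)
        self.params = {k: v.astype(dt) for k, v in p.items()}

    # ------------------------------------------------------------------ utils
    @property
    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    def _split_heads(self, x: np.ndarray) -> np.ndarray:
        B, N, D = x.shape
        H = self.config.n_heads
        return x.reshape(B, N, H, D // H).transpose(0, 2, 1, 3)

    def _merge_heads(self, x: np.ndarray) -> np.ndarray:
        B, H, N, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, N, H * dh)

    # ---------------------------------------------------------------- forward
    def forward(
        self,
        tokens: np.ndarray,
        return_attention: bool = False,
        need_cache: bool = False,
    ):
        """Run the encoder.

        Returns ``(hidden, logits, attention, cache)``: last-layer token
        outputs of shape (B, N, D), decoder logits of shape (B, N, V),
        the stacked attention tensor (B, layers, heads, N, N) when requested
        (else None), and the backward cache when requested (else None).
        """
        c = self.config
        p = self.params
        tokens = np.asarray(tokens)
        if tokens.ndim == 1:
            tokens = tokens[None, :]
        if tokens.max() >= c.vocab_size or tokens.min() < 0:
            raise ValueError("token id out of vocabulary range")
        B, N = tokens.shape
        if N > c.max_len:
            raise ValueError(f"sequence length {N} exceeds max_len {c.max_len}")
        pad = tokens == c.pad_id

        x = p["tok_emb"][tokens] + p["pos_emb"][None, :N]
        scale = 1.0 / math.sqrt(c.d_model // c.n_heads)
        key_mask = pad[:, None, None, :]  # broadcast over heads and queries
        attn_all = [] if return_attention else None
        caches = [] if need_cache else None

        for i in range(c.n_layers):
            a_in, ln1_cache = _layer_norm(x, p[f"l{i}.ln1_g"], p[f"l{i}.ln1_b"])
            q = self._split_heads(a_in @ p[f"l{i}.Wq"] + p[f"l{i}.wq_b"])
            k = self._split_heads(a_in @ p[f"l{i}.Wk"] + p[f"l{i}.wk_b"])
            v = self._split_heads(a_in @ p[f"l{i}.Wv"] + p[f"l{i}.wv_b"])
            scores = (q @ k.transpose(0, 1, 3, 2)) * scale
            np.copyto(scores, -np.inf, where=key_mask)
            scores -= scores.max(axis=-1, keepdims=True)
            attn = np.exp(scores, out=scores)
            attn /= attn.sum(axis=-1, keepdims=True)
            ctx = attn @ v
            merged = self._merge_heads(ctx)
            att_out = merged @ p[f"l{i}.Wo"] + p[f"l{i}.wo_b"]
            x1 = x + att_out
            f_in, ln2_cache = _layer_norm(x1, p[f"l{i}.ln2_g"], p[f"l{i}.ln2_b"])
            z = f_in @ p[f"l{i}.W1"] + p[f"l{i}.b1"]
            h = _gelu(z)
            f = h @ p[f"l{i}.W2"] + p[f"l{i}.b2"]
            x_next = x1 + f
            if return_attention:
                attn_all.append(attn)
            if need_cache:
                caches.append(
                    dict(a_in=a_in, q=q, k=k, v=v, attn=attn, merged=merged,
                         ln1=ln1_cache, f_in=f_in, z=z, h=h, ln2=ln2_cache)
                )
            x = x_next

        y, lnf_cache = _layer_norm(x, p["lnf_g"], p["lnf_b"])
        dec_W = p["tok_emb"].T if c.tie_decoder else p["dec_W"]
        logits = y @ dec_W + p["dec_b"]
        attention = np.stack(attn_all, axis=1) if return_attention else None
        cache = None
        if need_cache:
            cache = dict(tokens=tokens, pad=pad, layers=caches, hidden=y,
                         lnf=lnf_cache, scale=scale)
        return y, logits, attention, cache

    # --------------------------------------------------------------- backward
    def backward(
        self,
        cache: dict,
        d_logits: np.ndarray | None = None,
        d_hidden: np.ndarray | None = None,
    ) -> dict[str, np.ndarray]:
        """Backpropagate gradients of a scalar loss.

        ``d_logits`` is the loss gradient w.r.t. the decoder logits and/or
        ``d_hidden`` w.r.t. the last-layer token outputs; at least one must
        be given. Returns a gradient dict keyed like ``self.params``.
        """
        if d_logits is None and d_hidden is None:
            raise ValueError("provide d_logits and/or d_hidden")
        c = self.config
        p = self.params
        g = self.zero_grads()
        tokens = cache["tokens"]
        hidden = cache["hidden"]
        B, N = tokens.shape

        dy = np.zeros_like(hidden)
        if d_hidden is not None:
            dy += d_hidden
        if d_logits is not None:
            dec_W = p["tok_emb"].T if c.tie_decoder else p["dec_W"]
            dy += d_logits @ dec_W.T
            g["dec_b"] += d_logits.sum(axis=(0, 1))
            dW = hidden.reshape(-1, hidden.shape[-1]).T @ d_logits.reshape(-1, d_logits.shape[-1])
            if c.tie_decoder:
                g["tok_emb"] += dW.T
            else:
                g["dec_W"] += dW
        dx, dgf, dbf = _layer_norm_backward(dy, p["lnf_g"], cache["lnf"])
        g["lnf_g"] += dgf
        g["lnf_b"] += dbf

        for i in reversed(range(c.n_layers)):
            cc = cache["layers"][i]
            # FFN sub-block: x_next = x1 + W2 gelu(W1 LN2(x1) + b1) + b2
            df = dx
            g[f"l{i}.b2"] += df.sum(axis=(0, 1))
            g[f"l{i}.W2"] += cc["h"].reshape(-1, cc["h"].shape[-1]).T @ df.reshape(-1, df.shape[-1])
            dh = df @ p[f"l{i}.W2"].T
            dz = dh * _gelu_grad(cc["z"])
            g[f"l{i}.b1"] += dz.sum(axis=(0, 1))
            g[f"l{i}.W1"] += cc["f_in"].reshape(-1, cc["f_in"].shape[-1]).T @ dz.reshape(-1, dz.shape[-1])
            df_in = dz @ p[f"l{i}.W1"].T
            dx1_ln, dg2, db2 = _layer_norm_backward(df_in, p[f"l{i}.ln2_g"], cc["ln2"])
            g[f"l{i}.ln2_g"] += dg2
            g[f"l{i}.ln2_b"] += db2
            dx1 = dx + dx1_ln  # residual + normalized branch
            # attention sub-block: x1 = x + Wo·attend(LN1(x)) + bo
            datt_out = dx1
            g[f"l{i}.wo_b"] += datt_out.sum(axis=(0, 1))
            g[f"l{i}.Wo"] += cc["merged"].reshape(-1, cc["merged"].shape[-1]).T @ datt_out.reshape(-1, datt_out.shape[-1])
            dmerged = datt_out @ p[f"l{i}.Wo"].T
            dctx = self._split_heads(dmerged)
            dattn = dctx @ cc["v"].transpose(0, 1, 3, 2)
            dv = cc["attn"].transpose(0, 1, 3, 2) @ dctx
            # softmax backward (masked entries have attn == 0, so dscores == 0)
            a = cc["attn"]
            dscores = a * (dattn - (dattn * a).sum(axis=-1, keepdims=True))
            dscores *= cache["scale"]
            dq = dscores @ cc["k"]
            dk = dscores.transpose(0, 1, 3, 2) @ cc["q"]
            da_in = np.zeros_like(cc["a_in"])
            for name, dz_h in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
                dflat = self._merge_heads(dz_h)
                g[f"l{i}.{name}"] += cc["a_in"].reshape(-1, cc["a_in"].shape[-1]).T @ dflat.reshape(-1, dflat.shape[-1])
                g[f"l{i}.{name.lower()}_b"] += dflat.sum(axis=(0, 1))
                da_in = da_in + dflat @ p[f"l{i}.{name}"].T
            dx_ln, dg1, db1 = _layer_norm_backward(da_in, p[f"l{i}.ln1_g"], cc["ln1"])
            g[f"l{i}.ln1_g"] += dg1
            g[f"l{i}.ln1_b"] += db1
            dx = dx1 + dx_ln

        np.add.at(g["tok_emb"], tokens, dx)
        g["pos_emb"][:N] += dx.sum(axis=0)
        return g

    # ------------------------------------------------------------------- io
    def save(self, path) -> None:
        """Single binary archive with the config embedded."""
        buf = {f"param.{k}": v for k, v in self.params.items()}
        buf["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez_compressed(path, **buf)

    @classmethod
    def load(cls, path) -> "EncoderModel":
        with np.load(path) as data:
            cfg = EncoderConfig(**json.loads(bytes(data["config_json"]).decode()))
            model = cls(cfg, seed=0)
            for k in model.params:
                model.params[k] = data[f"param.{k}"]
        return model


def build_model(config: EncoderConfig, seed: int = 0) -> EncoderModel:
    """Construct a freshly initialized encoder (Xavier weights, zero biases);
    deterministic for a fixed seed."""
    return EncoderModel(config, seed=seed)
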