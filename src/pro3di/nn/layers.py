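"""Transformer building blocks on top of the autograd core."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np

from .autograd import Tensor, dropout, embedding, layer_norm, relu, softmax

NEG_INF = np.float32(-1e9)


class Module:
    """Parameter container with flat named access for optimizers and I/O."""

    def __init__(self) -> None:
        self._params: Dict[str, Tensor] = {}
        self._modules: Dict[str, "Module"] = {}

    def param(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array, requires_grad=True)
        self._params[name] = t
        return t

    def add_module(self, name: str, module: "Module") -> "Module":
        self._modules[name] = module
        return module

    def parameters(self, prefix: str = "") -> Dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, mod in self._modules.items():
            out.update(mod.parameters(prefix + name + "."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise ValueError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = state[k].astype(p.data.dtype).copy()


def _init(rng: np.random.Generator, *shape, scale: float = 0.02) -> np.ndarray:
    return rng.normal(0.0, scale, size=shape).astype(np.float32)


class Linear(Module):
    def __init__(self, rng, d_in: int, d_out: int, bias: bool = True):
        super().__init__()
        self.w = self.param("w", _init(rng, d_in, d_out))
        self.b = self.param("b", np.zeros(d_out, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w
        return y + self.b if self.b is not None else y


class LayerNorm(Module):
    def __init__(self, d: int):
        super().__init__()
        self.g = self.param("g", np.ones(d, dtype=np.float32))
        self.b = self.param("b", np.zeros(d, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.g, self.b)


class RelativeBias(Module):
    """Learned additive attention bias over clipped query/key offsets.

    Offsets key_pos - query_pos are clipped to [-max_offset, max_offset];
    each head owns one bias value per offset bucket. This gives the model a
    cheap, length-generalizing notion of position, which suits the nearly
    monotone residue-to-residue alignment of sequence/structure translation.
    """

    def __init__(self, rng, n_heads: int, max_offset: int = 8,
                 peaks: Optional[Sequence[int]] = None, slope: float = 1.5):
        super().__init__()
        self.max_offset = max_offset
        table = _init(rng, 2 * max_offset + 1, n_heads)
        if peaks is not None:
            # locality prior: head h starts focused near offset peaks[h % len];
            # translation here is (nearly) monotone residue-to-residue, so
            # biasing heads towards small offsets speeds up learning without
            # constraining what they can converge to.
            offsets = np.arange(-max_offset, max_offset + 1, dtype=np.float32)
            for h in range(table.shape[1]):
                table[:, h] += -slope * np.abs(offsets - peaks[h % len(peaks)])
        self.table = self.param("table", table)

    def __call__(self, n_q: int, n_k: int) -> Tensor:
        offsets = np.arange(n_k)[None, :] - np.arange(n_q)[:, None]
        idx = np.clip(offsets, -self.max_offset, self.max_offset) + self.max_offset
        bias = embedding(self.table, idx)  # (n_q, n_k, H)
        return bias.transpose(2, 0, 1)  # (H, n_q, n_k)


class MultiHeadAttention(Module):
    def __init__(self, rng, d_model: int, n_heads: int, max_offset: int = 8,
                 bias_peaks: Optional[Sequence[int]] = None):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.h = n_heads
        self.dk = d_model // n_heads
        self.q = self.add_module("q", Linear(rng, d_model, d_model, bias=False))
        self.k = self.add_module("k", Linear(rng, d_model, d_model, bias=False))
        self.v = self.add_module("v", Linear(rng, d_model, d_model, bias=False))
        self.o = self.add_module("o", Linear(rng, d_model, d_model, bias=False))
        self.bias = self.add_module("bias", RelativeBias(rng, n_heads, max_offset, peaks=bias_peaks))

    def _split(self, x: Tensor, b: int, l: int) -> Tensor:
        return x.reshape(b, l, self.h, self.dk).transpose(0, 2, 1, 3)

    def __call__(
        self,
        x_q: Tensor,
        x_kv: Tensor,
        key_pad: Optional[np.ndarray] = None,
        causal: bool = False,
    ) -> Tensor:
        b, lq, d = x_q.shape
        lk = x_kv.shape[1]
        q = self._split(self.q(x_q), b, lq)
        k = self._split(self.k(x_kv), b, lk)
        v = self._split(self.v(x_kv), b, lk)
        scores = (q @ k.transpose(0, 1, 3, 2)) * np.float32(1.0 / np.sqrt(self.dk))
        scores = scores + self.bias(lq, lk)  # broadcast over batch
        mask = np.zeros((b, 1, lq, lk), dtype=np.float32)
        if key_pad is not None:
            mask += np.where(key_pad[:, None, None, :], NEG_INF, 0.0)
        if causal:
            tri = np.triu(np.full((lq, lk), NEG_INF, dtype=np.float32), k=1)
            mask += tri[None, None]
        scores = scores + Tensor(mask)
        attn = softmax(scores, axis=-1)
        ctx = attn @ v  # (b, h, lq, dk)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(b, lq, d)
        return self.o(ctx)


class FeedForward(Module):
    def __init__(self, rng, d_model: int, d_ff: int):
        super().__init__()
        self.w1 = self.add_module("w1", Linear(rng, d_model, d_ff))
        self.w2 = self.add_module("w2", Linear(rng, d_ff, d_model))

    def __call__(self, x: Tensor) -> Tensor:
        return self.w2(relu(self.w1(x)))


class EncoderLayer(Module):
    """Pre-norm encoder block; attention heads start with local peaks around 0."""

    def __init__(self, rng, d_model: int, n_heads: int, d_ff: int):
        super().__init__()
        self.ln1 = self.add_module("ln1", LayerNorm(d_model))
        self.attn = self.add_module(
            "attn", MultiHeadAttention(rng, d_model, n_heads, bias_peaks=(-2, -1, 1, 2))
        )
        self.ln2 = self.add_module("ln2", LayerNorm(d_model))
        self.ff = self.add_module("ff", FeedForward(rng, d_model, d_ff))

    def __call__(self, x: Tensor, pad: np.ndarray) -> Tensor:
        h = self.ln1(x)
        x = x + self.attn(h, h, key_pad=pad)
        return x + self.ff(self.ln2(x))


class DecoderLayer(Module):
    def __init__(self, rng, d_model: int, n_heads: int, d_ff: int):
        super().__init__()
        self.ln1 = self.add_module("ln1", LayerNorm(d_model))
        self.self_attn = self.add_module(
            "self_attn", MultiHeadAttention(rng, d_model, n_heads, bias_peaks=(-1, -2, -3, 0))
        )
        self.ln2 = self.add_module("ln2", LayerNorm(d_model))
        # the encoder input carries a direction prefix, so decoder position i
        # lines up with encoder position i + 1
        self.cross_attn = self.add_module(
            "cross_attn", MultiHeadAttention(rng, d_model, n_heads, bias_peaks=(1, 0, 2, 1))
        )
        self.ln3 = self.add_module("ln3", LayerNorm(d_model))
        self.ff = self.add_module("ff", FeedForward(rng, d_model, d_ff))

    def __call__(
        self, x: Tensor, enc: Tensor, enc_pad: np.ndarray, dec_pad: np.ndarray
    ) -> Tensor:
        h = self.ln1(x)
        x = x + self.self_attn(h, h, key_pad=dec_pad, causal=True)
        x = x + self.cross_attn(self.ln2(x), enc, key_pad=enc_pad)
        return x + self.ff(self.ln3(x))
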