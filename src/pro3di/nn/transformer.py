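"""A small encoder-decoder translation model with tied embeddings.

Architecture class: shared token embedding, bidirectional self-attention
encoder, autoregressive decoder with causal self-attention and
cross-attention over the encoder states, learned relative-position biases,
and an output projection tied to the input embedding. Sized for single-CPU
toy training while keeping the architecture of full-scale translation models.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .autograd import Tensor, cross_entropy, embedding, no_grad
from .layers import DecoderLayer, EncoderLayer, LayerNorm, Module, _init


@dataclass
class ModelConfig:
    vocab_size: int
    d_model: int = 64
    n_heads: int = 4
    d_ff: int = 128
    n_encoder_layers: int = 2
    n_decoder_layers: int = 2
    max_len: int = 512
    seed: int = 0


class Seq2SeqModel(Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.embed = self.param("embed", _init(rng, cfg.vocab_size, cfg.d_model))
        self.enc_layers: List[EncoderLayer] = [
            self.add_module(f"enc{i}", EncoderLayer(rng, cfg.d_model, cfg.n_heads, cfg.d_ff))
            for i in range(cfg.n_encoder_layers)
        ]
        self.enc_ln = self.add_module("enc_ln", LayerNorm(cfg.d_model))
        self.dec_layers: List[DecoderLayer] = [
            self.add_module(f"dec{i}", DecoderLayer(rng, cfg.d_model, cfg.n_heads, cfg.d_ff))
            for i in range(cfg.n_decoder_layers)
        ]
        self.dec_ln = self.add_module("dec_ln", LayerNorm(cfg.d_model))

    # ------------------------------------------------------------------
    def encode(self, enc_ids: np.ndarray, pad_id: int) -> Tuple[Tensor, np.ndarray]:
        """Run the bidirectional encoder. Returns (states, pad mask)."""
        if enc_ids.shape[1] > self.cfg.max_len:
            raise ValueError(
                f"input length {enc_ids.shape[1]} exceeds positional capacity {self.cfg.max_len}"
            )
        pad = enc_ids == pad_id
        x = embedding(self.embed_tensor, enc_ids)
        for layer in self.enc_layers:
            x = layer(x, pad)
        return self.enc_ln(x), pad

    def decode(
        self, dec_ids: np.ndarray, enc: Tensor, enc_pad: np.ndarray, pad_id: int
    ) -> Tensor:
        """Teacher-forced decoder pass; returns logits (B, Lt, V)."""
        dec_pad = dec_ids == pad_id
        # position 0 is the conventional decoder start token (pad id) and must
        # stay attendable, otherwise the first query row is fully masked
        dec_pad = dec_pad.copy()
        dec_pad[:, 0] = False
        x = embedding(self.embed_tensor, dec_ids)
        for layer in self.dec_layers:
            x = layer(x, enc, enc_pad, dec_pad)
        x = self.dec_ln(x)
        b, l, d = x.shape
        logits = x.reshape(b * l, d) @ self.embed_tensor.transpose(1, 0)
        return logits.reshape(b, l, self.cfg.vocab_size)

    @property
    def embed_tensor(self) -> Tensor:
        return self._params["embed"]

    # ------------------------------------------------------------------
    def loss(
        self,
        enc_ids: np.ndarray,
        targets: np.ndarray,
        pad_id: int,
        decoder_start_id: Optional[int] = None,
        count_exclude_id: Optional[int] = None,
    ) -> Tuple[Tensor, float, int]:
        """Cross-entropy of ``targets`` given ``enc_ids`` (teacher forcing).

        The decoder input is the target sequence shifted right, opened by the
        pad token (conventional decoder start). Pad positions in the target
        carry no loss. ``count_exclude_id`` drops one extra token id (e.g.
        end-of-sequence) from the accuracy counts only — useful when accuracy
        should reflect content tokens rather than the stop decision. Returns
        (loss, n_correct, n_tokens).
        """
        start = pad_id if decoder_start_id is None else decoder_start_id
        dec_in = np.concatenate(
            [np.full((targets.shape[0], 1), start, dtype=targets.dtype), targets[:, :-1]],
            axis=1,
        )
        enc, enc_pad = self.encode(enc_ids, pad_id)
        logits = self.decode(dec_in, enc, enc_pad, pad_id)
        b, l, v = logits.shape
        flat_targets = targets.reshape(-1)
        mask = (flat_targets != pad_id).astype(np.float32)
        count_mask = None
        if count_exclude_id is not None:
            count_mask = mask * (flat_targets != count_exclude_id)
        return cross_entropy(logits.reshape(b * l, v), flat_targets, mask, count_mask)

    def step_logits(
        self,
        prefix_ids: np.ndarray,
        enc: Tensor,
        enc_pad: np.ndarray,
        pad_id: int,
        positions: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        """Next-token logits for each row of ``prefix_ids`` (generation step).

        ``positions[i]`` selects the column holding row i's last real token
        (rows may be right-padded to a common width); by default the final
        column is used for every row.
        """
        with no_grad():
            logits = self.decode(prefix_ids, enc, enc_pad, pad_id)
        if positions is None:
            return logits.data[:, -1, :]
        rows = np.arange(prefix_ids.shape[0])
        return logits.data[rows, np.asarray(positions), :]

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = {
            "vocab_size": self.cfg.vocab_size,
            "d_model": self.cfg.d_model,
            "n_heads": self.cfg.n_heads,
            "d_ff": self.cfg.d_ff,
            "n_encoder_layers": self.cfg.n_encoder_layers,
            "n_decoder_layers": self.cfg.n_decoder_layers,
            "max_len": self.cfg.max_len,
            "seed": self.cfg.seed,
        }
        np.savez(path, __meta__=np.array(list(meta.items()), dtype=object), **self.state_dict())

    @classmethod
    def load(cls, path) -> "Seq2SeqModel":
        with np.load(path, allow_pickle=True) as payload:
            meta = {k: int(v) for k, v in payload["__meta__"]}
            state = {k: payload[k] for k in payload.files if k != "__meta__"}
        model = cls(ModelConfig(**meta))
        model.load_state_dict(state)
        return model
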