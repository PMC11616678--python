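"""Fast inference path: a two-layer CNN over frozen encoder embeddings.

Instead of token-by-token decoding, each residue's structure token is
classified directly from the encoder's last-layer embedding by two 1-D
convolutions (embedding -> hidden -> 20 states) with a ReLU between. A
confidence threshold on the per-residue max probability trades coverage
(low threshold) against precision (high threshold); below-threshold
residues are emitted as the lower-case placeholder ``x`` so output stays
length-aligned with the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .nn import Adam, Tensor, cross_entropy, no_grad, relu
from .nn.autograd import dropout as _dropout, embedding as _gather, pad_rows
from .nn.layers import Linear, Module
from .records import TDI_ALPHABET, ProteinRecord
from .seq2seq import encoder_embed_batch
from .vocabulary import BilingualVocabulary

MASK_CHAR = "x"  # not a structure token; marks below-threshold residues


@dataclass
class HeadConfig:
    kernel_size: int = 7
    hidden_channels: int = 32
    dropout: float = 0.1
    epochs: int = 12
    lr: float = 1e-3
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError("kernel_size must be odd so output length equals input length")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")


class Conv1d(Module):
    """Same-length 1-D convolution via window gather + matmul."""

    def __init__(self, rng, d_in: int, d_out: int, kernel: int):
        super().__init__()
        self.kernel = kernel
        self.half = kernel // 2
        self.proj = self.add_module("proj", Linear(rng, kernel * d_in, d_out))

    def __call__(self, x: Tensor) -> Tensor:
        b, l, d = x.shape
        padded = pad_rows(x.transpose(1, 0, 2), self.half, self.half)  # (L+2h, B, d)
        idx = np.arange(l)[:, None] + np.arange(self.kernel)[None, :]
        windows = _gather(padded, idx)  # (L, k, B, d)
        windows = windows.transpose(2, 0, 1, 3).reshape(b, l, self.kernel * d)
        return self.proj(windows)


class CNNHead(Module):
    def __init__(self, d_model: int, cfg: HeadConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.conv1 = self.add_module("conv1", Conv1d(rng, d_model, cfg.hidden_channels, cfg.kernel_size))
        self.conv2 = self.add_module(
            "conv2", Conv1d(rng, cfg.hidden_channels, len(TDI_ALPHABET), cfg.kernel_size)
        )

    def __call__(self, x: Tensor, training: bool = False, rng=None) -> Tensor:
        h = relu(self.conv1(x))
        if training and self.cfg.dropout > 0:
            h = _dropout(h, self.cfg.dropout, rng, training=True)
        return self.conv2(h)

    def save_dir(self, path) -> None:
        import json
        from pathlib import Path

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        d_model = self.conv1.proj.w.data.shape[0] // self.cfg.kernel_size
        with open(path / "head_config.json", "w") as fh:
            json.dump(
                {
                    "d_model": d_model,
                    "kernel_size": self.cfg.kernel_size,
                    "hidden_channels": self.cfg.hidden_channels,
                    "dropout": self.cfg.dropout,
                    "epochs": self.cfg.epochs,
                    "lr": self.cfg.lr,
                    "batch_size": self.cfg.batch_size,
                    "seed": self.cfg.seed,
                },
                fh,
            )
        np.savez(path / "head.npz", **self.state_dict())

    @classmethod
    def load_dir(cls, path) -> "CNNHead":
        import json
        from pathlib import Path

        path = Path(path)
        with open(path / "head_config.json") as fh:
            meta = json.load(fh)
        d_model = meta.pop("d_model")
        head = cls(d_model, HeadConfig(**meta))
        with np.load(path / "head.npz") as payload:
            head.load_state_dict({k: payload[k] for k in payload.files})
        return head


@dataclass
class PerResiduePrediction:
    """Per-residue structure-token prediction with confidences."""

    labels: str
    probabilities: np.ndarray  # (L, 20), rows sum to 1
    confidence: np.ndarray  # (L,), max probability per residue
    flagged: np.ndarray  # (L,) bool, confidence below the threshold

    @property
    def coverage(self) -> float:
        return float(1.0 - self.flagged.mean()) if len(self.labels) else 0.0

    @property
    def masked_labels(self) -> str:
        """Labels with below-threshold residues replaced by the placeholder."""
        return "".join(
            MASK_CHAR if f else c for c, f in zip(self.labels, self.flagged)
        )


def _label_indices(tdi_seq: str) -> np.ndarray:
    index = {c: i for i, c in enumerate(TDI_ALPHABET)}
    return np.fromiter((index[c] for c in tdi_seq), dtype=np.int64, count=len(tdi_seq))


def train_head(
    embeddings: Sequence[np.ndarray],
    tdi_labels: Sequence[str],
    cfg: HeadConfig,
) -> CNNHead:
    """Train the classifier on frozen per-residue embeddings.

    ``embeddings[i]`` is the (L_i, d) matrix for protein i, aligned with the
    structure-token string ``tdi_labels[i]``.
    """
    if len(embeddings) != len(tdi_labels):
        raise ValueError("need one label string per embedding matrix")
    for e, lab in zip(embeddings, tdi_labels):
        if e.shape[0] != len(lab):
            raise ValueError("embedding rows must match label length")
    d_model = embeddings[0].shape[1]
    head = CNNHead(d_model, cfg)
    rng = np.random.default_rng(cfg.seed)
    n = len(embeddings)
    order_pool = np.arange(n)
    labels_idx = [_label_indices(lab) for lab in tdi_labels]
    for _ in range(cfg.epochs):
        rng.shuffle(order_pool)
        opt = getattr(head, "_opt", None)
        if opt is None:
            opt = Adam(head.parameters(), lr=cfg.lr)
            head._opt = opt
        for i in range(0, n, cfg.batch_size):
            batch = order_pool[i : i + cfg.batch_size]
            x, y, mask = _pad_embedding_batch(
                [embeddings[j] for j in batch], [labels_idx[j] for j in batch]
            )
            logits = head(Tensor(x), training=True, rng=rng)
            b, l, v = logits.shape
            loss, _, _ = cross_entropy(logits.reshape(b * l, v), y.reshape(-1), mask.reshape(-1))
            head.zero_grad()
            loss.backward()
            opt.step()
    return head


def _pad_embedding_batch(
    embeddings: List[np.ndarray], labels: List[np.ndarray]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    b = len(embeddings)
    lmax = max(e.shape[0] for e in embeddings)
    d = embeddings[0].shape[1]
    x = np.zeros((b, lmax, d), dtype=np.float32)
    y = np.zeros((b, lmax), dtype=np.int64)
    mask = np.zeros((b, lmax), dtype=np.float32)
    for i, (e, lab) in enumerate(zip(embeddings, labels)):
        x[i, : e.shape[0]] = e
        y[i, : lab.shape[0]] = lab
        mask[i, : lab.shape[0]] = 1.0
    return x, y, mask


def head_probabilities(head: CNNHead, embedding_matrix: np.ndarray) -> np.ndarray:
    """Row-stochastic (L, 20) probability matrix for one protein."""
    with no_grad():
        logits = head(Tensor(embedding_matrix[None, :, :])).data[0]
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z.astype(np.float64))
    return e / e.sum(axis=1, keepdims=True)


def predict_3di(
    model,
    head: CNNHead,
    record: ProteinRecord,
    vocab: BilingualVocabulary,
    threshold: float = 0.0,
) -> PerResiduePrediction:
    """Predict structure tokens for one amino-acid sequence.

    Residues whose maximum class probability falls below ``threshold`` are
    flagged (and masked in ``masked_labels``); coverage is the unflagged
    fraction.
    """
    from .seq2seq import encoder_embed

    emb = encoder_embed(model, record, vocab, alphabet="AA")
    probs = head_probabilities(head, emb)
    best = probs.argmax(axis=1)
    confidence = probs.max(axis=1)
    labels = "".join(TDI_ALPHABET[i] for i in best)
    return PerResiduePrediction(
        labels=labels,
        probabilities=probs,
        confidence=confidence,
        flagged=confidence < threshold,
    )


def predict_3di_batch(
    model,
    head: CNNHead,
    records: Sequence[ProteinRecord],
    vocab: BilingualVocabulary,
    threshold: float = 0.0,
) -> List[PerResiduePrediction]:
    embs = encoder_embed_batch(model, records, vocab, alphabet="AA")
    out = []
    for emb in embs:
        probs = head_probabilities(head, emb)
        best = probs.argmax(axis=1)
        confidence = probs.max(axis=1)
        out.append(
            PerResiduePrediction(
                labels="".join(TDI_ALPHABET[i] for i in best),
                probabilities=probs,
                confidence=confidence,
                flagged=confidence < threshold,
            )
        )
    return out


def q20_accuracy(
    predictions: Sequence[PerResiduePrediction],
    records: Sequence[ProteinRecord],
    respect_flags: bool = False,
) -> float:
    """Per-residue 20-state accuracy against the records' structure tokens.

    With ``respect_flags`` only unflagged (confident) residues count — the
    precision of the thresholded output.
    """
    correct = total = 0
    for pred, rec in zip(predictions, records):
        for i, (p, t) in enumerate(zip(pred.labels, rec.tdi_seq)):
            if respect_flags and pred.flagged[i]:
                continue
            correct += p == t
            total += 1
    if total == 0:
        raise ValueError("no residues to score (all flagged?)")
    return correct / total
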