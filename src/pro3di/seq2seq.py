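"""Two-phase denoising/translation training of the bilingual model.

Phase 1 continues span-based denoising on *both* modalities (amino-acid and
structure-token strings, alternating per batch) so the model learns the new
lower-case tokens without catastrophically forgetting the other alphabet.
Phase 2 trains the actual translation objective in both directions
simultaneously, alternating direction per batch, under a max-length schedule
that starts short and grows.

The published full-scale recipe uses learning rates 1e-3 (denoising) and
1e-5 (translation) with lengths truncated to 256 and later 512 over
100K + 600K steps; :func:`full_scale_train_config` records those values. The toy
defaults in :class:`TrainConfig` scale the schedule down to minutes on one
CPU while keeping its shape (short phase 1, longer phase 2, growing length
cap, same corruption rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .nn import Adam, ModelConfig, Seq2SeqModel, no_grad
from .records import ProteinRecord
from .vocabulary import BilingualVocabulary

logger = logging.getLogger("pro3di.seq2seq")


# ---------------------------------------------------------------------------
# span corruption
# ---------------------------------------------------------------------------

@dataclass
class CorruptionSample:
    """One span-denoising example.

    ``input_ids`` is the original sequence with each masked span replaced by
    one sentinel; ``target_ids`` lists each sentinel followed by the tokens it
    hides, closed by the next unused sentinel and end-of-sequence. The
    corruption is invertible: :func:`reconstruct` recovers the original.
    """

    input_ids: List[int]
    target_ids: List[int]


def span_corrupt(
    ids: Sequence[int],
    rate: float,
    mean_span: float,
    rng: np.random.Generator,
    vocab: BilingualVocabulary,
) -> CorruptionSample:
    """T5-style span corruption of a token sequence (no EOS, no sentinels).

    The number of spans is ``round(len * rate / mean_span)`` and span lengths
    are geometric with the requested mean, so the expected masked fraction is
    ``rate``. Spans never overlap; the i-th span is replaced by sentinel i.
    """
    ids = list(ids)
    if any(vocab.is_sentinel(i) for i in ids):
        raise ValueError("input already contains sentinel tokens")
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    n = len(ids)
    n_spans = int(round(n * rate / mean_span)) if rate > 0 else 0
    if n_spans == 0:
        return CorruptionSample(ids + [vocab.eos_id], [vocab.sentinel_id(0), vocab.eos_id])
    if n_spans > vocab.n_sentinel - 1:
        raise ValueError(
            f"{n_spans} spans exceed the {vocab.n_sentinel} available sentinels"
        )
    lengths = rng.geometric(1.0 / mean_span, size=n_spans)
    # shrink greedily if the draw cannot fit the sequence
    while lengths.sum() > n:
        lengths[lengths.argmax()] -= 1
    total_masked = int(lengths.sum())
    # distribute the unmasked tokens into n_spans + 1 gaps
    free = n - total_masked
    cuts = np.sort(rng.integers(0, free + 1, size=n_spans))
    gaps = np.diff(np.concatenate([[0], cuts, [free]]))

    input_ids: List[int] = []
    target_ids: List[int] = []
    pos = 0
    for i in range(n_spans):
        g = int(gaps[i])
        input_ids.extend(ids[pos : pos + g])
        pos += g
        span_len = int(lengths[i])
        input_ids.append(vocab.sentinel_id(i))
        target_ids.append(vocab.sentinel_id(i))
        target_ids.extend(ids[pos : pos + span_len])
        pos += span_len
    input_ids.extend(ids[pos:])
    target_ids.append(vocab.sentinel_id(n_spans))
    input_ids.append(vocab.eos_id)
    target_ids.append(vocab.eos_id)
    return CorruptionSample(input_ids, target_ids)


def reconstruct(sample: CorruptionSample, vocab: BilingualVocabulary) -> List[int]:
    """Invert :func:`span_corrupt`, splicing masked spans back into the input."""
    spans: Dict[int, List[int]] = {}
    current: Optional[int] = None
    for t in sample.target_ids:
        if vocab.is_sentinel(t):
            current = t
            spans[current] = []
        elif t == vocab.eos_id:
            current = None
        elif current is not None:
            spans[current].append(t)
    out: List[int] = []
    for t in sample.input_ids:
        if vocab.is_sentinel(t):
            out.extend(spans.get(t, []))
        elif t != vocab.eos_id:
            out.append(t)
    return out


def masked_fraction(sample: CorruptionSample, vocab: BilingualVocabulary) -> float:
    n_masked = sum(
        1 for t in sample.target_ids if not vocab.is_sentinel(t) and t != vocab.eos_id
    )
    n_total = n_masked + sum(
        1
        for t in sample.input_ids
        if not vocab.is_sentinel(t) and t != vocab.eos_id
    )
    return n_masked / n_total if n_total else 0.0


# ---------------------------------------------------------------------------
# translation batches
# ---------------------------------------------------------------------------

def make_translation_batch(
    records: Sequence[ProteinRecord],
    direction: str,
    max_len: int,
    vocab: BilingualVocabulary,
) -> List[Tuple[List[int], List[int]]]:
    """Tokenized (encoder input, decoder target) pairs for paired records.

    ``direction='both'`` emits one sample per direction per record, doubling
    the sample count. Sequences are truncated to ``max_len`` residues before
    tokenization.
    """
    if direction not in ("AA2fold", "fold2AA", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    out: List[Tuple[List[int], List[int]]] = []
    for rec in records:
        if rec.aa_seq is None or rec.tdi_seq is None:
            raise ValueError(f"record {rec.id!r} is not paired (needs AA and 3Di)")
        aa = rec.aa_seq[:max_len]
        tdi = rec.tdi_seq[:max_len]
        if direction in ("AA2fold", "both"):
            out.append((vocab.encode(aa, "AA2fold"), vocab.encode(tdi, "none")))
        if direction in ("fold2AA", "both"):
            out.append((vocab.encode(tdi, "fold2AA"), vocab.encode(aa, "none")))
    return out


def pad_batch(
    samples: Sequence[Tuple[List[int], List[int]]], pad_id: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Stack variable-length (input, target) id lists into padded arrays."""
    max_in = max(len(s[0]) for s in samples)
    max_out = max(len(s[1]) for s in samples)
    enc = np.full((len(samples), max_in), pad_id, dtype=np.int64)
    tgt = np.full((len(samples), max_out), pad_id, dtype=np.int64)
    for i, (x, y) in enumerate(samples):
        enc[i, : len(x)] = x
        tgt[i, : len(y)] = y
    return enc, tgt


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Two-phase schedule; defaults are the single-CPU toy scale.

    ``phase2_max_len_schedule`` lists (steps, max_len) stages, mirroring the
    published short-then-long curriculum. :func:`full_scale_train_config` holds the
    full-scale published values.
    """

    phase1_lr: float = 1e-3
    phase2_lr: float = 1e-3
    phase1_steps: int = 150
    phase1_max_len: int = 64
    phase2_max_len_schedule: Tuple[Tuple[int, int], ...] = ((800, 48), (500, 64))
    batch_size: int = 48
    grad_accum: int = 1
    corruption_rate: float = 0.15
    mean_span_len: float = 3.0
    eval_every: int = 200
    seed: int = 0
    model_dims: Tuple[int, int, int] = (1, 64, 4)  # (layers per stack, width, heads)

    def __post_init__(self) -> None:
        if not (0.0 < self.corruption_rate < 1.0):
            raise ValueError("corruption_rate must lie in (0, 1)")
        for name in ("phase1_lr", "phase2_lr", "phase1_steps", "batch_size", "grad_accum"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def full_scale_train_config() -> dict:
    """The published full-scale training hyperparameters, for reference."""
    return {
        "phase1_lr": 1e-3,
        "phase2_lr": 1e-5,
        "phase1_max_len": 256,
        "phase2_max_len_schedule": [(100_000, 256), (600_000, 512)],
        "batch_size": 16,
        "grad_accum_phase2": (1, 4),
    }


@dataclass
class TrainResult:
    model: Seq2SeqModel
    vocab: BilingualVocabulary
    trace: List[dict] = field(default_factory=list)

    def trace_frame(self):
        import pandas as pd

        return pd.DataFrame(self.trace)


def _sample_records(
    records: Sequence[ProteinRecord], batch_size: int, rng: np.random.Generator
) -> List[ProteinRecord]:
    idx = rng.integers(0, len(records), size=batch_size)
    return [records[i] for i in idx]


def train(
    records: Sequence[ProteinRecord],
    cfg: TrainConfig,
    vocab: Optional[BilingualVocabulary] = None,
    n_sentinel: int = 16,
    progress: bool = False,
) -> TrainResult:
    """Run both training phases on curated, paired, split records."""
    if vocab is None:
        vocab = BilingualVocabulary(n_sentinel=n_sentinel)
    train_recs = [r for r in records if r.split == "train"]
    val_recs = [r for r in records if r.split == "val"]
    if not train_recs:
        raise ValueError("empty train split")
    if not val_recs:
        raise ValueError("empty val split")

    n_layers, d_model, n_heads = cfg.model_dims
    model = Seq2SeqModel(
        ModelConfig(
            vocab_size=vocab.size,
            d_model=d_model,
            n_heads=n_heads,
            d_ff=2 * d_model,
            n_encoder_layers=n_layers,
            n_decoder_layers=n_layers,
            seed=cfg.seed,
        )
    )
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    trace: List[dict] = []

    # ---- phase 1: span denoising on both modalities, alternating ----------
    opt = Adam(model.parameters(), lr=cfg.phase1_lr, warmup_steps=min(50, cfg.phase1_steps))
    for step in range(cfg.phase1_steps):
        modality = "AA" if step % 2 == 0 else "3Di"
        model.zero_grad()
        for _ in range(cfg.grad_accum):
            batch = _sample_records(train_recs, cfg.batch_size, rng)
            samples = []
            for rec in batch:
                seq = rec.aa_seq if modality == "AA" else rec.tdi_seq
                ids = vocab.encode(seq[: cfg.phase1_max_len], "none")[:-1]  # strip EOS
                s = span_corrupt(ids, cfg.corruption_rate, cfg.mean_span_len, rng, vocab)
                samples.append((s.input_ids, s.target_ids))
            enc, tgt = pad_batch(samples, vocab.pad_id)
            loss, correct, total = model.loss(enc, tgt, vocab.pad_id)
            loss.backward()
        opt.step()
        if step % 25 == 0 or step == cfg.phase1_steps - 1:
            trace.append(
                {
                    "phase": 1,
                    "step": step,
                    "modality": modality,
                    "loss": float(loss.data),
                    "acc": correct / total,
                }
            )
            if progress:
                logger.info("phase1 step %d (%s): loss %.3f", step, modality, float(loss.data))

    # per-modality denoising health check: both alphabets must remain
    # assigned finite loss after the mixed phase-1 curriculum
    for modality in ("AA", "3Di"):
        trace.append(
            {
                "phase": 1,
                "step": cfg.phase1_steps,
                "modality": modality,
                "val_denoise_loss": evaluate_denoising(
                    model, val_recs, vocab, modality, cfg, seed=cfg.seed
                ),
            }
        )

    # ---- phase 2: bidirectional translation, alternating direction --------
    opt = Adam(model.parameters(), lr=cfg.phase2_lr, warmup_steps=100)
    global_step = 0
    for stage_steps, max_len in cfg.phase2_max_len_schedule:
        for _ in range(stage_steps):
            direction = "AA2fold" if global_step % 2 == 0 else "fold2AA"
            model.zero_grad()
            for _ in range(cfg.grad_accum):
                batch = _sample_records(train_recs, cfg.batch_size, rng)
                samples = make_translation_batch(batch, direction, max_len, vocab)
                enc, tgt = pad_batch(samples, vocab.pad_id)
                loss, correct, total = model.loss(enc, tgt, vocab.pad_id)
                loss.backward()
            opt.step()
            if global_step % cfg.eval_every == 0:
                val_loss, val_acc = evaluate_translation(
                    model, val_recs, vocab, "AA2fold", max_len, cfg.batch_size
                )
                trace.append(
                    {
                        "phase": 2,
                        "step": global_step,
                        "modality": direction,
                        "loss": float(loss.data),
                        "acc": correct / total,
                        "val_loss": val_loss,
                        "val_acc": val_acc,
                    }
                )
                if progress:
                    logger.info(
                        "phase2 step %d: train loss %.3f, val acc %.3f",
                        global_step,
                        float(loss.data),
                        val_acc,
                    )
            elif global_step % 50 == 0:
                trace.append(
                    {
                        "phase": 2,
                        "step": global_step,
                        "modality": direction,
                        "loss": float(loss.data),
                        "acc": correct / total,
                    }
                )
            global_step += 1
    return TrainResult(model=model, vocab=vocab, trace=trace)


def evaluate_translation(
    model: Seq2SeqModel,
    records: Sequence[ProteinRecord],
    vocab: BilingualVocabulary,
    direction: str,
    max_len: int = 64,
    batch_size: int = 64,
) -> Tuple[float, float]:
    """Teacher-forced loss and residue-token accuracy of a translation direction.

    The accuracy counts residue positions only: the end-of-sequence decision
    is predictable from length alone, so including it would inflate accuracy
    on contentless data and blur the comparison against marginal baselines.
    """
    samples = make_translation_batch(records, direction, max_len, vocab)
    losses, correct, total = [], 0, 0
    with no_grad():
        for i in range(0, len(samples), batch_size):
            enc, tgt = pad_batch(samples[i : i + batch_size], vocab.pad_id)
            loss, c, t = model.loss(enc, tgt, vocab.pad_id, count_exclude_id=vocab.eos_id)
            losses.append(float(loss.data) * max(t, 1))
            correct += c
            total += t
    return sum(losses) / total, correct / total


def evaluate_denoising(
    model: Seq2SeqModel,
    records: Sequence[ProteinRecord],
    vocab: BilingualVocabulary,
    modality: str,
    cfg: TrainConfig,
    seed: int = 0,
) -> float:
    """Span-denoising loss of one modality (phase-1 health check)."""
    rng = np.random.default_rng(seed)
    samples = []
    for rec in records:
        seq = rec.aa_seq if modality == "AA" else rec.tdi_seq
        ids = vocab.encode(seq[: cfg.phase1_max_len], "none")[:-1]
        s = span_corrupt(ids, cfg.corruption_rate, cfg.mean_span_len, rng, vocab)
        samples.append((s.input_ids, s.target_ids))
    losses, total = [], 0
    with no_grad():
        for i in range(0, len(samples), cfg.batch_size):
            enc, tgt = pad_batch(samples[i : i + cfg.batch_size], vocab.pad_id)
            loss, _, t = model.loss(enc, tgt, vocab.pad_id)
            losses.append(float(loss.data) * t)
            total += t
    return sum(losses) / total


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

def encoder_embed(
    model: Seq2SeqModel,
    record: ProteinRecord,
    vocab: BilingualVocabulary,
    alphabet: str = "AA",
) -> np.ndarray:
    """Per-residue embeddings from the encoder's last layer.

    The sequence is encoded exactly as the encoder sees it during translation
    (direction prefix + residues + EOS); prefix and EOS rows are dropped so
    one row remains per residue.
    """
    if alphabet == "AA":
        ids = vocab.encode(record.aa_seq, "AA2fold")
    elif alphabet == "3Di":
        ids = vocab.encode(record.tdi_seq, "fold2AA")
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    with no_grad():
        states, _ = model.encode(np.asarray([ids], dtype=np.int64), vocab.pad_id)
    return states.data[0, 1:-1, :].copy()


def encoder_embed_batch(
    model: Seq2SeqModel,
    records: Sequence[ProteinRecord],
    vocab: BilingualVocabulary,
    alphabet: str = "AA",
    batch_size: int = 64,
) -> List[np.ndarray]:
    """Batched :func:`encoder_embed` (pad-aware), one matrix per record."""
    out: List[np.ndarray] = []
    order = np.argsort([r.length for r in records], kind="stable")
    buf: Dict[int, np.ndarray] = {}
    for i in range(0, len(order), batch_size):
        chunk = [records[j] for j in order[i : i + batch_size]]
        ids = [
            vocab.encode(r.aa_seq if alphabet == "AA" else r.tdi_seq,
                         "AA2fold" if alphabet == "AA" else "fold2AA")
            for r in chunk
        ]
        enc, _ = pad_batch([(x, [vocab.pad_id]) for x in ids], vocab.pad_id)
        with no_grad():
            states, _pad = model.encode(enc, vocab.pad_id)
        for row, rec_idx, x in zip(states.data, order[i : i + batch_size], ids):
            buf[int(rec_idx)] = row[1 : len(x) - 1, :].copy()
    return [buf[i] for i in range(len(records))]


def mean_pool(embedding_matrix: np.ndarray) -> np.ndarray:
    """Average-pool residue embeddings into one fixed-length protein vector."""
    if embedding_matrix.ndim != 2 or embedding_matrix.shape[0] == 0:
        raise ValueError("need a non-empty (L, d) embedding matrix")
    return embedding_matrix.mean(axis=0)
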