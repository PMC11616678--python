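"""Autoregressive generation with the full sampling stack.

The logit pipeline applies, in this fixed order: repetition penalty,
temperature, top-k truncation, nucleus (top-p) truncation, an optional
target-alphabet constraint, and a final softmax. The order follows the
convention of the generation framework the published configurations were
written for; reordering would change the sampled distribution.

Two published generation configurations ship as factories:
:func:`aa2fold_config` (sequence -> structure tokens: sampling with 3 beams,
top-p 0.95, temperature 1.2, top-k 6, repetition penalty 1.2) and
:func:`fold2aa_config` (structure tokens -> sequence: top-p 0.85,
temperature 1.0, top-k 3, repetition penalty 1.2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .nn import Seq2SeqModel, Tensor, no_grad
from .vocabulary import BilingualVocabulary

NEG_INF = -np.inf


@dataclass
class DecodeConfig:
    """Sampling knobs; the defaults are the published AA->3Di configuration."""

    do_sample: bool = True
    num_beams: int = 3
    temperature: float = 1.2
    top_p: float = 0.95
    top_k: int = 6  # 0 disables the budget
    repetition_penalty: float = 1.2
    max_new_tokens: int = 80
    seed: int = 0
    constrain_alphabet: bool = True

    def __post_init__(self) -> None:
        if self.num_beams < 1:
            raise ValueError("num_beams must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not (0.0 < self.top_p <= 1.0):
            raise ValueError("top_p must lie in (0, 1]")
        if self.top_k < 0:
            raise ValueError("top_k must be >= 0")
        if self.repetition_penalty < 1.0:
            raise ValueError("repetition_penalty must be >= 1")


def aa2fold_config(**overrides) -> DecodeConfig:
    """Published sampling configuration for sequence -> structure tokens."""
    return replace(DecodeConfig(), **overrides)


def fold2aa_config(**overrides) -> DecodeConfig:
    """Published sampling configuration for structure tokens -> sequence."""
    base = DecodeConfig(
        do_sample=True,
        num_beams=1,
        temperature=1.0,
        top_p=0.85,
        top_k=3,
        repetition_penalty=1.2,
    )
    return replace(base, **overrides)


def process_logits(
    logits: np.ndarray,
    generated_so_far: Sequence[int],
    cfg: DecodeConfig,
    allowed_ids: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Turn raw next-token logits into the sampling distribution.

    Steps, in order: (1) repetition penalty — each already-generated token's
    logit is divided by the penalty if positive, multiplied by it if negative;
    (2) temperature scaling; (3) top-k truncation; (4) nucleus truncation
    keeping the minimal probability prefix reaching ``top_p`` (boundary token
    included); (5) optional alphabet constraint; (6) softmax. Raises if every
    token ends up masked.
    """
    z = np.asarray(logits, dtype=np.float64).copy()
    if z.ndim != 1:
        raise ValueError("process_logits expects a single logit vector")
    if not np.all(np.isfinite(z)):
        raise ValueError("logits must be finite")

    if cfg.repetition_penalty != 1.0 and len(generated_so_far) > 0:
        seen = np.unique(np.asarray(generated_so_far, dtype=np.int64))
        pos = z[seen] > 0
        z[seen[pos]] /= cfg.repetition_penalty
        z[seen[~pos]] *= cfg.repetition_penalty

    z /= cfg.temperature

    if cfg.top_k > 0 and cfg.top_k < z.size:
        # stable order: ties broken towards the lower index
        order = np.lexsort((np.arange(z.size), -z))
        z[order[cfg.top_k :]] = NEG_INF

    if cfg.top_p < 1.0:
        finite = np.isfinite(z)
        zmax = z[finite].max()
        probs = np.zeros_like(z)
        probs[finite] = np.exp(z[finite] - zmax)
        probs /= probs.sum()
        order = np.lexsort((np.arange(z.size), -probs))
        csum = np.cumsum(probs[order])
        # small tolerance so exact-boundary sums are not pushed out by rounding
        cutoff = int(np.searchsorted(csum, cfg.top_p - 1e-9, side="left"))
        z[order[cutoff + 1 :]] = NEG_INF

    if allowed_ids is not None:
        mask = np.full(z.size, NEG_INF)
        mask[np.asarray(allowed_ids, dtype=np.int64)] = 0.0
        z += mask

    finite = np.isfinite(z)
    if not finite.any():
        raise ValueError("all tokens masked after logit processing")
    zmax = z[finite].max()
    out = np.zeros_like(z)
    out[finite] = np.exp(z[finite] - zmax)
    out /= out.sum()
    return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _allowed_ids(vocab: BilingualVocabulary, direction: str) -> List[int]:
    # X is excluded from generated amino acids: it is a reading convention for
    # ambiguous input, not a residue to design.
    target = vocab.tdi_ids() if direction == "AA2fold" else [
        vocab.token_to_id[t] for t in vocab.aa_tokens if t != "X"
    ]
    return target + [vocab.eos_id]


def translate(
    model: Seq2SeqModel,
    seq: str,
    direction: str,
    cfg: DecodeConfig,
    vocab: BilingualVocabulary,
) -> str:
    """Generate the translation of ``seq`` under the given sampling config.

    ``num_beams == 1`` runs ancestral sampling (or greedy when
    ``do_sample=False``); ``num_beams > 1`` runs beam search, stochastic when
    sampling is on: each beam extends by sampling from its processed
    distribution, beams are ranked by length-normalized log-probability, and
    the best finished beam is returned. Deterministic given ``cfg.seed``.
    """
    if direction not in ("AA2fold", "fold2AA"):
        raise ValueError(f"invalid direction {direction!r}")
    rng = np.random.default_rng(cfg.seed)
    enc_ids = np.asarray([vocab.encode(seq, direction)], dtype=np.int64)
    with no_grad():
        enc, enc_pad = model.encode(enc_ids, vocab.pad_id)
    allowed = _allowed_ids(vocab, direction) if cfg.constrain_alphabet else None

    n = cfg.num_beams
    if n > 1:
        enc = Tensor(np.repeat(enc.data, n, axis=0))
        enc_pad = np.repeat(enc_pad, n, axis=0)

    # beam state; with num_beams == 1 this degenerates to ancestral sampling
    beams: List[List[int]] = [[] for _ in range(n)]
    scores = np.zeros(n)
    finished = np.zeros(n, dtype=bool)

    for _ in range(cfg.max_new_tokens):
        prefix = _prefixes(beams, vocab.pad_id)
        positions = np.array([len(b) for b in beams])
        logits = model.step_logits(prefix, enc, enc_pad, vocab.pad_id, positions=positions)
        if allowed is not None:
            # restrict the candidate set up front so the top-k/top-p budgets
            # are spent inside the target alphabet; the processor's own
            # alphabet mask then never fires on an empty set
            keep = np.full(logits.shape[1], -1e9)
            keep[allowed] = 0.0
            logits = logits + keep
        for b in range(n):
            if finished[b]:
                continue
            probs = process_logits(logits[b], beams[b], cfg, allowed_ids=allowed)
            if cfg.do_sample:
                token = int(rng.choice(probs.size, p=probs))
            else:
                token = int(probs.argmax())
            scores[b] += np.log(probs[token] + 1e-30)
            beams[b].append(token)
            if token == vocab.eos_id:
                finished[b] = True
        if finished.all():
            break

    norm = np.array([s / max(len(b), 1) for s, b in zip(scores, beams)])
    pool = np.flatnonzero(finished) if finished.any() else np.arange(n)
    best = pool[int(np.argmax(norm[pool]))]  # argmax ties break to lower index
    return vocab.decode(beams[best])


def _prefixes(beams: List[List[int]], pad_id: int) -> np.ndarray:
    # decoder input: start token (pad) followed by the generated ids
    width = 1 + max(len(b) for b in beams)
    out = np.full((len(beams), width), pad_id, dtype=np.int64)
    for i, b in enumerate(beams):
        out[i, 1 : 1 + len(b)] = b
    return out
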