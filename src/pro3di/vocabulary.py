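"""Bilingual character-level vocabulary for amino acids and 3Di tokens.

Amino acids are the 20 upper-case letters (plus X for ambiguous residues);
structure tokens are the same 20 letters lower-cased, which keeps the two
alphabets disjoint inside one vocabulary. Two direction prefixes select the
translation direction (<AA2fold>: sequence -> structure tokens; <fold2AA>:
the inverse), and a configurable block of sentinel tokens supports span
corruption. Tokenization is strictly character-level: one token per residue.
"""

from __future__ import annotations

import json
from typing import Dict, Iterable, List, Optional

from .records import AA_ALPHABET, TDI_ALPHABET

PAD = "<pad>"
EOS = "</s>"
UNK = "<unk>"
AA2FOLD = "<AA2fold>"
FOLD2AA = "<fold2AA>"

DIRECTIONS = ("AA2fold", "fold2AA", "none")


class BilingualVocabulary:
    """Token <-> id bijection over both alphabets, prefixes, sentinels, specials."""

    def __init__(self, n_sentinel: int = 128) -> None:
        if n_sentinel < 1:
            raise ValueError("need at least one sentinel token")
        self.n_sentinel = n_sentinel
        self.specials = [PAD, EOS, UNK]
        self.prefix_tokens = [AA2FOLD, FOLD2AA]
        self.aa_tokens = list(AA_ALPHABET) + ["X"]
        self.tdi_tokens = list(TDI_ALPHABET)
        self.sentinel_tokens = [f"<extra_id_{i}>" for i in range(n_sentinel)]
        tokens = (
            self.specials
            + self.prefix_tokens
            + self.aa_tokens
            + self.tdi_tokens
            + self.sentinel_tokens
        )
        assert not (set(self.aa_tokens) & set(self.tdi_tokens)), "alphabets must be disjoint"
        assert len(set(tokens)) == len(tokens), "token list must be collision-free"
        self.token_to_id: Dict[str, int] = {t: i for i, t in enumerate(tokens)}
        self.id_to_token: Dict[int, str] = {i: t for t, i in self.token_to_id.items()}

    # -- well-known ids ----------------------------------------------------
    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def eos_id(self) -> int:
        return self.token_to_id[EOS]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    def sentinel_id(self, i: int) -> int:
        return self.token_to_id[self.sentinel_tokens[i]]

    def prefix_id(self, direction: str) -> int:
        return self.token_to_id[AA2FOLD if direction == "AA2fold" else FOLD2AA]

    @property
    def size(self) -> int:
        return len(self.token_to_id)

    def aa_ids(self) -> List[int]:
        return [self.token_to_id[t] for t in self.aa_tokens]

    def tdi_ids(self) -> List[int]:
        return [self.token_to_id[t] for t in self.tdi_tokens]

    def is_sentinel(self, idx: int) -> bool:
        first = self.token_to_id[self.sentinel_tokens[0]]
        return first <= idx < first + self.n_sentinel

    # -- encode / decode ---------------------------------------------------
    def encode(self, seq: str, direction: str = "none") -> List[int]:
        """Tokenize ``seq``; prepend the direction prefix, append end-of-sequence.

        ``direction='none'`` infers the alphabet from casing and adds no
        prefix. Mixed-case or out-of-vocabulary input raises.
        """
        if direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {direction!r}")
        has_upper = any(c.isupper() for c in seq)
        has_lower = any(c.islower() for c in seq)
        if has_upper and has_lower:
            raise ValueError("mixed-case sequence: cannot be both AA and 3Di")
        if direction == "AA2fold" and has_lower:
            raise ValueError("AA2fold expects an upper-case amino-acid input")
        if direction == "fold2AA" and has_upper:
            raise ValueError("fold2AA expects a lower-case 3Di input")
        ids: List[int] = []
        if direction != "none":
            ids.append(self.prefix_id(direction))
        for c in seq:
            idx = self.token_to_id.get(c)
            if idx is None:
                raise ValueError(f"character {c!r} not in vocabulary")
            ids.append(idx)
        ids.append(self.eos_id)
        return ids

    def decode(self, ids: Iterable[int]) -> str:
        """Drop prefixes, sentinels, pad and EOS; concatenate residue tokens."""
        chars: List[str] = []
        for idx in ids:
            token = self.id_to_token.get(int(idx))
            if token is None:
                raise ValueError(f"unknown token id {idx}")
            if len(token) == 1:
                chars.append(token)
        return "".join(chars)

    # -- serialization -----------------------------------------------------
    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"n_sentinel": self.n_sentinel, "token_to_id": self.token_to_id}, fh)

    @classmethod
    def from_json(cls, path) -> "BilingualVocabulary":
        with open(path) as fh:
            payload = json.load(fh)
        vocab = cls(n_sentinel=payload["n_sentinel"])
        if vocab.token_to_id != payload["token_to_id"]:
            raise ValueError("serialized vocabulary is incompatible with this construction")
        return vocab
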