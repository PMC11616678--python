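"""Core domain records shared across the package.

A :class:`ProteinRecord` carries one protein in the two modalities this
package models: the amino-acid sequence (20 upper-case letters) and the
3Di structure-token string (20 lower-case letters, one token per residue
describing its local tertiary geometry). Optional metadata — a pLDDT-like
per-protein quality score, a sequence-cluster id, a hierarchical structure
label (fold/superfamily/family, CATH/SCOPe-style) and a train/val/test
split tag — drive curation, splitting and benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: 3Di structure alphabet, written lower-case to disambiguate from amino acids.
TDI_ALPHABET = "acdefghiklmnpqrstvwy"

AA_SET = frozenset(AA_ALPHABET) | {"X"}
TDI_SET = frozenset(TDI_ALPHABET)

#: Rare/ambiguous amino-acid codes folded into X so lengths stay intact.
AMBIGUOUS_AA = {"B", "Z", "U", "O", "J"}

SPLITS = ("train", "val", "test", "unassigned")


@dataclass(frozen=True, order=True)
class HierarchyLabel:
    """Hierarchical structure label, coarse to fine (e.g. fold/superfam/family).

    Comparisons between labels are level-prefix comparisons: two labels
    "match at level k" iff they agree on levels 0..k.
    """

    levels: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("HierarchyLabel needs at least one level")

    def __len__(self) -> int:
        return len(self.levels)

    def matches_at(self, other: "HierarchyLabel", level: int) -> bool:
        """True iff self and other agree on all levels 0..level (inclusive)."""
        if level >= len(self.levels) or level >= len(other.levels):
            raise IndexError(f"level {level} out of range")
        return self.levels[: level + 1] == other.levels[: level + 1]

    @classmethod
    def parse(cls, text: str, sep: str = ".") -> "HierarchyLabel":
        return cls(tuple(text.split(sep)))

    def __str__(self) -> str:
        return ".".join(self.levels)


@dataclass
class ProteinRecord:
    """One protein with paired sequence/structure strings and metadata."""

    id: str
    aa_seq: Optional[str] = None
    tdi_seq: Optional[str] = None
    plddt: Optional[float] = None
    cluster_id: Optional[str] = None
    hierarchy: Optional[HierarchyLabel] = None
    split: str = "unassigned"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.aa_seq is not None:
            bad = [(i, c) for i, c in enumerate(self.aa_seq) if c not in AA_SET]
            if bad:
                i, c = bad[0]
                raise ValueError(
                    f"record {self.id!r}: invalid amino-acid letter {c!r} at position {i + 1}"
                )
        if self.tdi_seq is not None:
            bad = [(i, c) for i, c in enumerate(self.tdi_seq) if c not in TDI_SET]
            if bad:
                i, c = bad[0]
                raise ValueError(
                    f"record {self.id!r}: invalid 3Di letter {c!r} at position {i + 1}"
                )
        if self.aa_seq is not None and self.tdi_seq is not None:
            if len(self.aa_seq) != len(self.tdi_seq):
                raise ValueError(
                    f"record {self.id!r}: AA length {len(self.aa_seq)} != 3Di length {len(self.tdi_seq)}"
                )
        if self.plddt is not None and not (0.0 <= self.plddt <= 100.0):
            raise ValueError(f"record {self.id!r}: pLDDT {self.plddt} outside [0, 100]")
        if self.split not in SPLITS:
            raise ValueError(f"record {self.id!r}: unknown split {self.split!r}")

    @property
    def length(self) -> int:
        seq = self.aa_seq if self.aa_seq is not None else self.tdi_seq
        return 0 if seq is None else len(seq)

    def with_(self, **kwargs) -> "ProteinRecord":
        """Return a shallow copy with the given fields replaced."""
        return replace(self, **kwargs)


def check_unique_ids(records: Sequence[ProteinRecord]) -> None:
    seen = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate record id {r.id!r}")
        seen.add(r.id)
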