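"""Readers and writers for the package's on-disk formats.

Amino-acid and 3Di strings live in *separate* standard FASTA files joined
by record id (the 3Di dialect simply uses the 20 lower-case letters).
Substitution matrices use the whitespace-delimited square-table format of
structure-search tools (header row/column of alphabet letters). Per-protein
metadata travels in a TSV with columns id, plddt, cluster_id, hierarchy,
split. Run configuration is YAML.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    AA_SET,
    AMBIGUOUS_AA,
    TDI_ALPHABET,
    TDI_SET,
    HierarchyLabel,
    ProteinRecord,
    check_unique_ids,
)

logger = logging.getLogger("pro3di")


def setup_logging(level: int = logging.INFO) -> None:
    """Route package log lines to stderr with a terse format."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("pro3di")
    root.handlers[:] = [handler]
    root.setLevel(level)


class FastaParseError(ValueError):
    pass


class AlphabetError(ValueError):
    pass


def read_fasta(path, alphabet: str) -> List[ProteinRecord]:
    """Read a FASTA file into validated records.

    Parameters
    ----------
    path:
        FASTA file. Any line wrapping is accepted.
    alphabet:
        ``"AA"`` for upper-case amino acids (B/Z/U/O/J silently become X with
        a warning) or ``"3Di"`` for the lower-case structure-token dialect.
    """
    if alphabet not in ("AA", "3Di"):
        raise ValueError(f"alphabet must be 'AA' or '3Di', got {alphabet!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _sanity_check_fasta(path)

    records: List[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if alphabet == "AA":
            seq, n_mapped = _map_ambiguous_aa(seq)
            if n_mapped:
                logger.warning(
                    "record %s: mapped %d ambiguous amino-acid letter(s) to X",
                    rec.id,
                    n_mapped,
                )
            _validate_alphabet(rec.id, seq, AA_SET, "amino-acid")
            records.append(ProteinRecord(id=rec.id, aa_seq=seq))
        else:
            _validate_alphabet(rec.id, seq, TDI_SET, "3Di")
            records.append(ProteinRecord(id=rec.id, tdi_seq=seq))
    check_unique_ids(records)
    return records


def _sanity_check_fasta(path: Path) -> None:
    """Reject files whose first non-blank line is not a FASTA header."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: expected FASTA header line starting with '>'"
                )
            return


def _map_ambiguous_aa(seq: str) -> Tuple[str, int]:
    n = sum(seq.count(c) for c in AMBIGUOUS_AA)
    if n:
        table = str.maketrans({c: "X" for c in AMBIGUOUS_AA})
        seq = seq.translate(table)
    return seq, n


def _validate_alphabet(rec_id: str, seq: str, allowed, kind: str) -> None:
    for i, c in enumerate(seq):
        if c not in allowed:
            raise AlphabetError(
                f"record {rec_id!r}: invalid {kind} character {c!r} at position {i + 1}"
            )


def write_fasta(path, records: Sequence[ProteinRecord], alphabet: str, width: int = 60) -> None:
    """Write records to FASTA, wrapping lines at ``width`` characters."""
    seqs = []
    for r in records:
        seq = r.aa_seq if alphabet == "AA" else r.tdi_seq
        if seq is None:
            raise ValueError(f"record {r.id!r} lacks a {alphabet} sequence")
        seqs.append(SeqRecord(Seq(seq), id=r.id, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def pair_records(
    aa: Sequence[ProteinRecord], tdi: Sequence[ProteinRecord]
) -> List[ProteinRecord]:
    """Join AA and 3Di records on id; drop (and log) mismatches.

    Records whose AA and 3Di lengths differ, or that lack a partner in the
    other file, are dropped with a warning; the total dropped count is logged.
    Duplicate ids within either input raise.
    """
    check_unique_ids(aa)
    check_unique_ids(tdi)
    tdi_by_id = {r.id: r for r in tdi}
    paired: List[ProteinRecord] = []
    dropped = 0
    for a in aa:
        t = tdi_by_id.pop(a.id, None)
        if t is None:
            logger.warning("record %s: no 3Di partner; dropped", a.id)
            dropped += 1
            continue
        if len(a.aa_seq) != len(t.tdi_seq):
            logger.warning(
                "record %s: length mismatch (AA %d vs 3Di %d); dropped",
                a.id,
                len(a.aa_seq),
                len(t.tdi_seq),
            )
            dropped += 1
            continue
        paired.append(a.with_(tdi_seq=t.tdi_seq))
    for t in tdi_by_id.values():
        logger.warning("record %s: no AA partner; dropped", t.id)
        dropped += 1
    if dropped:
        logger.warning("pair_records: dropped %d record(s)", dropped)
    return paired


@dataclass
class SubstitutionMatrix:
    """Square integer substitution matrix over a token alphabet, plus gap costs.

    ``gap_open`` is charged for the first residue of a gap and ``gap_extend``
    for each further residue; both are <= 0.
    """

    alphabet: str
    scores: np.ndarray
    gap_open: int = -10
    gap_extend: int = -1

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int64)
        n = len(self.alphabet)
        if self.scores.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.scores.shape} does not match alphabet size {n}"
            )
        if len(set(self.alphabet)) != n:
            raise ValueError("alphabet letters must be unique")
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        self.index = {c: i for i, c in enumerate(self.alphabet)}

    def score(self, a: str, b: str) -> int:
        return int(self.scores[self.index[a], self.index[b]])

    def encode(self, seq: str) -> np.ndarray:
        try:
            return np.fromiter((self.index[c] for c in seq), dtype=np.int64, count=len(seq))
        except KeyError as e:
            raise AlphabetError(f"character {e.args[0]!r} not in matrix alphabet") from None


def read_substitution_matrix(
    path, gap_open: int = -10, gap_extend: int = -1, strict: bool = True
) -> SubstitutionMatrix:
    """Read a whitespace-delimited square matrix with a letter header row/column.

    Letters are matched case-insensitively and stored lower-case. With
    ``strict=True`` the alphabet must have exactly 20 letters (the 3Di
    alphabet); ``strict=False`` admits reduced toy alphabets.
    """
    rows = []
    header: Optional[List[str]] = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if header is None:
                header = [f.lower() for f in fields]
                continue
            rows.append(fields)
    if header is None or not rows:
        raise ValueError(f"{path}: empty substitution matrix file")
    n = len(header)
    if strict and n != 20:
        raise ValueError(f"{path}: expected a 20-letter alphabet, found {n}")
    if len(rows) != n:
        raise ValueError(f"{path}: matrix is not square ({len(rows)} rows, {n} columns)")
    mat = np.zeros((n, n), dtype=np.int64)
    for i, fields in enumerate(rows):
        if len(fields) == n + 1:  # leading row letter
            if fields[0].lower() != header[i]:
                raise ValueError(f"{path}: row label {fields[0]!r} does not match header")
            fields = fields[1:]
        if len(fields) != n:
            raise ValueError(f"{path}: row {i + 1} has {len(fields)} values, expected {n}")
        mat[i] = [int(round(float(x))) for x in fields]
    if not np.array_equal(mat, mat.T):
        raise ValueError(f"{path}: matrix is not symmetric")
    return SubstitutionMatrix("".join(header), mat, gap_open=gap_open, gap_extend=gap_extend)


def write_substitution_matrix(path, mat: SubstitutionMatrix) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(mat.alphabet) + "\n")
        for i, c in enumerate(mat.alphabet):
            fh.write(c + " " + " ".join(str(int(x)) for x in mat.scores[i]) + "\n")


def default_tdi_matrix(gap_open: int = -10, gap_extend: int = -1) -> SubstitutionMatrix:
    """A simple symmetric 3Di-style scoring model: +6 match, -2 mismatch.

    Synthetic stand-in for a structure-alphabet substitution matrix; the real
    matrix of a structure-search tool can be loaded with
    :func:`read_substitution_matrix`.
    """
    n = len(TDI_ALPHABET)
    scores = np.full((n, n), -2, dtype=np.int64)
    np.fill_diagonal(scores, 6)
    return SubstitutionMatrix(TDI_ALPHABET, scores, gap_open=gap_open, gap_extend=gap_extend)


METADATA_COLUMNS = ["id", "plddt", "cluster_id", "hierarchy", "split"]


def write_metadata(path, records: Sequence[ProteinRecord]) -> None:
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "plddt": [r.plddt for r in records],
            "cluster_id": [r.cluster_id for r in records],
            "hierarchy": [str(r.hierarchy) if r.hierarchy else None for r in records],
            "split": [r.split for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "cluster_id": str, "hierarchy": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metadata TSV lacks column(s) {missing}")
    return df


def attach_metadata(records: Sequence[ProteinRecord], df: pd.DataFrame) -> List[ProteinRecord]:
    by_id: Dict[str, dict] = {str(row.id): row for row in df.itertuples(index=False)}
    out = []
    for r in records:
        row = by_id.get(r.id)
        if row is None:
            out.append(r)
            continue
        hierarchy = (
            HierarchyLabel.parse(row.hierarchy) if isinstance(row.hierarchy, str) else r.hierarchy
        )
        out.append(
            r.with_(
                plddt=None if pd.isna(row.plddt) else float(row.plddt),
                cluster_id=row.cluster_id if isinstance(row.cluster_id, str) else r.cluster_id,
                hierarchy=hierarchy,
                split=row.split if isinstance(row.split, str) else r.split,
            )
        )
    return out


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
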