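"""Global alignment, sequence-level generation metrics and roundtrip filtering.

The aligner is a Gotoh-style global Needleman-Wunsch with affine gaps
(``gap_open`` charged for the first gap residue, ``gap_extend`` for each
further one) over an arbitrary substitution matrix, with a fully
deterministic traceback (ties prefer diagonal, then up, then left).
PIDE is percentage identity over alignment columns (gap columns included by
default); similarity is the percentage of aligned pairs with a positive
substitution score.

Roundtrip accuracy scores an amino-acid sequence generated from a native
structure-token string by translating it back to structure tokens and
aligning against the native string: high roundtrip identity indicates the
generated sequence encodes the intended structure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numba import njit
from scipy.stats import entropy as _kl_divergence

from .decoding import DecodeConfig, translate
from .io import SubstitutionMatrix
from .records import AA_ALPHABET
from .vocabulary import BilingualVocabulary

NEG = np.int64(-(10**15))


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: int
    pide: float
    similarity: float

    @property
    def length(self) -> int:
        return len(self.aligned_a)


@njit(cache=False)
def _gotoh_fill(a, b, scores, open_, ext):  # pragma: no cover - numba kernel
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (vertical / "up")
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal / "left")
    # pointers: predecessor state 0=M, 1=X, 2=Y (3 = none/boundary)
    PM = np.full((n + 1, m + 1), 3, dtype=np.int8)
    PX = np.full((n + 1, m + 1), 3, dtype=np.int8)
    PY = np.full((n + 1, m + 1), 3, dtype=np.int8)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = open_ + (i - 1) * ext
        PX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = open_ + (j - 1) * ext
        PY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = scores[a[i - 1], b[j - 1]]
            # M: diagonal move from best of (M, X, Y); tie order M > X > Y
            best, ptr = M[i - 1, j - 1], 0
            if X[i - 1, j - 1] > best:
                best, ptr = X[i - 1, j - 1], 1
            if Y[i - 1, j - 1] > best:
                best, ptr = Y[i - 1, j - 1], 2
            if best > NEG:
                M[i, j] = best + s
                PM[i, j] = ptr
            # X: consume a[i-1] against a gap
            best, ptr = M[i - 1, j] + open_, 0
            if X[i - 1, j] + ext > best:
                best, ptr = X[i - 1, j] + ext, 1
            if Y[i - 1, j] + open_ > best:
                best, ptr = Y[i - 1, j] + open_, 2
            X[i, j] = best
            PX[i, j] = ptr
            # Y: consume b[j-1] against a gap
            best, ptr = M[i, j - 1] + open_, 0
            if X[i, j - 1] + open_ > best:
                best, ptr = X[i, j - 1] + open_, 1
            if Y[i, j - 1] + ext > best:
                best, ptr = Y[i, j - 1] + ext, 2
            Y[i, j] = best
            PY[i, j] = ptr
    return M, X, Y, PM, PX, PY


def nw_align(
    a: str,
    b: str,
    mat: SubstitutionMatrix,
    pide_denominator: str = "alignment",
) -> AlignmentResult:
    """Optimal global alignment of ``a`` and ``b`` under affine gap costs.

    ``pide_denominator`` selects the identity denominator: the full alignment
    length including gap columns (default, conservative) or the shorter
    sequence length (``"shorter"``), for sensitivity analyses.
    """
    if pide_denominator not in ("alignment", "shorter"):
        raise ValueError("pide_denominator must be 'alignment' or 'shorter'")
    ia, ib = mat.encode(a), mat.encode(b)
    open_, ext = np.int64(mat.gap_open), np.int64(mat.gap_extend)
    if len(a) == 0 or len(b) == 0:
        gap_len = max(len(a), len(b))
        score = 0 if gap_len == 0 else int(open_ + (gap_len - 1) * ext)
        return _finish(a.ljust(gap_len, "-") if b == "" else "-" * gap_len,
                       b.ljust(gap_len, "-") if a == "" else "-" * gap_len,
                       score, mat, a, b, pide_denominator)
    M, X, Y, PM, PX, PY = _gotoh_fill(ia, ib, mat.scores, open_, ext)
    n, m = len(a), len(b)
    # final state choice honours the same tie order: diag(M) > up(X) > left(Y)
    state, best = 0, M[n, m]
    if X[n, m] > best:
        state, best = 1, X[n, m]
    if Y[n, m] > best:
        state, best = 2, Y[n, m]
    out_a: List[str] = []
    out_b: List[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            prev = PM[i, j]
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == 1:
            prev = PX[i, j]
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            prev = PY[i, j]
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        state = int(prev)
    return _finish("".join(reversed(out_a)), "".join(reversed(out_b)),
                   int(best), mat, a, b, pide_denominator)


def _finish(
    aligned_a: str,
    aligned_b: str,
    score: int,
    mat: SubstitutionMatrix,
    a: str,
    b: str,
    pide_denominator: str,
) -> AlignmentResult:
    length = len(aligned_a)
    if length == 0:
        return AlignmentResult("", "", score, 100.0, 100.0)
    identical = sum(x == y and x != "-" for x, y in zip(aligned_a, aligned_b))
    positive = sum(
        x != "-" and y != "-" and mat.score(x, y) > 0
        for x, y in zip(aligned_a, aligned_b)
    )
    denom = length if pide_denominator == "alignment" else max(min(len(a), len(b)), 1)
    return AlignmentResult(
        aligned_a,
        aligned_b,
        score,
        100.0 * identical / denom,
        100.0 * positive / denom,
    )


# ---------------------------------------------------------------------------
# naturalness
# ---------------------------------------------------------------------------

def aa_frequencies(sequences: Sequence[str]) -> np.ndarray:
    """Empirical distribution over the 20 standard amino acids (pooled)."""
    counts = np.zeros(20, dtype=np.float64)
    index = {c: i for i, c in enumerate(AA_ALPHABET)}
    for seq in sequences:
        for c in seq:
            if c in index:
                counts[index[c]] += 1
            elif c != "X":
                raise ValueError(f"unexpected character {c!r} in amino-acid sequence")
    total = counts.sum()
    if total == 0:
        raise ValueError("no amino acids observed")
    return counts / total


def kl_naturalness(generated: Sequence[str], reference_freqs: np.ndarray) -> float:
    """KL divergence (nats) of the pooled generated AA composition vs reference.

    Zero iff the compositions agree; the reference must be strictly positive.
    """
    if not generated:
        raise ValueError("no generated sequences")
    q = np.asarray(reference_freqs, dtype=np.float64)
    if q.shape != (20,) or np.any(q <= 0):
        raise ValueError("reference_freqs must be a strictly positive 20-vector")
    q = q / q.sum()
    p = aa_frequencies(generated)
    return float(_kl_divergence(p, q))


# ---------------------------------------------------------------------------
# roundtrip
# ---------------------------------------------------------------------------

@dataclass
class RoundtripResult:
    """Candidates from roundtrip-filtered generation.

    ``accepted`` is the best candidate when any reached the threshold, else
    None — in that case ``best`` still names the best-effort candidate.
    """

    candidates: List[Tuple[str, float]]
    accepted: Optional[str]
    n_attempts: int

    @property
    def best(self) -> Tuple[str, float]:
        return max(self.candidates, key=lambda c: c[1])


def roundtrip_accuracy(
    native_3di: str,
    generated_aa: str,
    model,
    cfg: DecodeConfig,
    mat: SubstitutionMatrix,
    vocab: BilingualVocabulary,
) -> float:
    """PIDE between native structure tokens and those re-predicted from the AA."""
    back = translate(model, generated_aa, "AA2fold", cfg, vocab)
    return nw_align(native_3di, back, mat).pide


def generate_with_roundtrip(
    native_3di: str,
    model,
    cfg_fwd: DecodeConfig,
    cfg_back: DecodeConfig,
    mat: SubstitutionMatrix,
    vocab: BilingualVocabulary,
    threshold: float = 70.0,
    budget: int = 10,
) -> RoundtripResult:
    """Sample AA candidates from a structure-token string until one roundtrips.

    Candidates are drawn with ``cfg_fwd`` (structure -> sequence) and scored by
    roundtrip accuracy under ``cfg_back`` (sequence -> structure); generation
    stops early once a candidate reaches ``threshold`` and never exceeds
    ``budget`` attempts. Deterministic given the config seeds.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    candidates: List[Tuple[str, float]] = []
    for attempt in range(budget):
        fwd = dc_replace(cfg_fwd, seed=cfg_fwd.seed + 1009 * attempt)
        back = dc_replace(cfg_back, seed=cfg_back.seed + 1009 * attempt)
        aa = translate(model, native_3di, "fold2AA", fwd, vocab)
        if not aa:
            candidates.append(("", 0.0))
            continue
        pide = roundtrip_accuracy(native_3di, aa, model, back, mat, vocab)
        candidates.append((aa, pide))
        if pide >= threshold:
            break
    best_aa, best_pide = max(candidates, key=lambda c: c[1])
    accepted = best_aa if best_pide >= threshold else None
    return RoundtripResult(candidates=candidates, accepted=accepted, n_attempts=len(candidates))
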