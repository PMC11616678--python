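"""Seeded generator of a toy bilingual protein universe.

The generator emulates the statistical structure the translation method
assumes, so every downstream stage (tokenization, training, decoding,
curation, benchmarking) is testable without external data:

* paired (AA, 3Di-like) strings in which each structure token is a local
  windowed function of the amino-acid sequence plus tunable positional noise;
* strong structure-token class imbalance (a handful of tokens covering more
  than half of all residues, as observed for real 3Di strings);
* run-length smoothing so tokens form secondary-structure-like runs;
* per-protein pLDDT-like quality scores with a controllable low-quality tail;
* sequence clusters nested inside a three-level fold/superfamily/family
  hierarchy, generated top-down with per-level mutation rates so both
  homology search and embedding-based annotation transfer have signal.

All randomness flows from a single seed through spawned child generators,
so worlds are byte-identical across runs for a fixed configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .records import AA_ALPHABET, TDI_ALPHABET, HierarchyLabel, ProteinRecord

N_AA = 20
N_TDI = 20

# Physicochemical classes of the 20 amino acids (ACDEFGHIKLMNPQRSTVWY order):
# 0 hydrophobic, 1 aromatic, 2 polar, 3 positive, 4 negative, 5 small/special.
# The window map g reads class patterns, not residue identities: local
# backbone geometry tracks residue character far more than exact identity,
# and it keeps the map learnable at desk scale.
AA_CLASS = np.array(
    [0, 0, 4, 4, 1, 5, 3, 0, 3, 0, 0, 2, 5, 2, 3, 2, 2, 0, 1, 1], dtype=np.uint64
)
N_CLASS = 6
_PAD_CLASS = N_CLASS  # boundary marker outside the class alphabet


@dataclass
class WorldConfig:
    """Configuration of the synthetic universe.

    window
        Width (odd) of the amino-acid context that determines each raw
        structure token.
    noise_rate
        Per-position probability that the final structure token is resampled
        uniformly, breaking the deterministic AA->token link.
    skew
        Geometric decay of the target token distribution (token i has prior
        mass proportional to ``skew**i``); 0.78 makes the three most common
        tokens cover slightly more than half of all residues, matching the
        imbalance seen in real structure-token data.
    hierarchy_shape
        (folds, superfamilies per fold, families per superfamily).
    low_quality_frac
        Expected fraction of proteins whose quality score falls below 70.
    """

    n_proteins: int = 6500
    length_range: Tuple[int, int] = (30, 60)
    window: int = 3
    noise_rate: float = 0.0
    skew: float = 0.78
    n_clusters: int = 108
    hierarchy_shape: Tuple[int, int, int] = (4, 3, 3)
    seed: int = 0
    low_quality_frac: float = 0.12
    # per-level mutation rates: fold->superfam, superfam->family,
    # family->cluster, cluster->protein
    mutation_rates: Tuple[float, float, float, float] = (0.35, 0.25, 0.15, 0.08)

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("length_range must satisfy 1 <= min <= max")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be an odd positive integer")
        if not (0.0 <= self.noise_rate <= 1.0):
            raise ValueError("noise_rate must lie in [0, 1]")
        if self.skew <= 0:
            raise ValueError("skew must be positive")
        if min(self.n_proteins, self.n_clusters, *self.hierarchy_shape) < 1:
            raise ValueError("all counts must be >= 1")
        if not (0.0 <= self.low_quality_frac <= 1.0):
            raise ValueError("low_quality_frac must lie in [0, 1]")


def token_prior(skew: float) -> np.ndarray:
    """Skewed target distribution over the 20 structure tokens."""
    p = skew ** np.arange(N_TDI, dtype=np.float64)
    return p / p.sum()


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Fixed 64-bit avalanche hash (vectorized); defines the window map g."""
    z = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    z ^= z >> np.uint64(30)
    z = (z * np.uint64(0xBF58476D1CE4E5B9)).astype(np.uint64)
    z ^= z >> np.uint64(27)
    z = (z * np.uint64(0x94D049BB133111EB)).astype(np.uint64)
    z ^= z >> np.uint64(31)
    return z


@lru_cache(maxsize=8)
def _g_table(window: int, skew: float) -> np.ndarray:
    """The fixed surjective map g: class-window key -> structure token.

    All ``(N_CLASS + 1) ** window`` possible window keys are ordered by a
    fixed avalanche hash of the key (pseudo-random but seed-independent) and
    partitioned into contiguous blocks sized by the skewed token prior, each
    token receiving at least one key. The resulting map is surjective, has
    the configured output imbalance under near-uniform key usage, and can be
    recomputed exactly from any amino-acid sequence.
    """
    n_keys = (N_CLASS + 1) ** window
    order = np.argsort(_splitmix64(np.arange(n_keys, dtype=np.uint64)), kind="stable")
    p = token_prior(skew)
    quota = np.maximum(1, np.round(p * n_keys).astype(np.int64))
    # largest-remainder style fix-up so quotas sum to the key count exactly
    while quota.sum() > n_keys:
        quota[int(np.argmax(quota))] -= 1
    while quota.sum() < n_keys:
        quota[int(np.argmax(p - quota / n_keys))] += 1
    table = np.empty(n_keys, dtype=np.int64)
    start = 0
    for token, q in enumerate(quota):
        table[order[start : start + q]] = token
        start += q
    return table


def window_map(aa_idx: np.ndarray, window: int, skew: float) -> np.ndarray:
    """Raw structure tokens: g(aa[i-w..i+w]) for every position.

    g reads the physicochemical class pattern of the window (boundaries get
    their own class) and maps it through :func:`_g_table`. It depends only on
    the window content, never on the world seed, so a generated world can be
    verified by recomputing g.
    """
    half = (window - 1) // 2
    classes = AA_CLASS[aa_idx.astype(np.int64)]
    padded = np.concatenate(
        [np.full(half, _PAD_CLASS), classes, np.full(half, _PAD_CLASS)]
    ).astype(np.uint64)
    key = np.zeros(len(aa_idx), dtype=np.uint64)
    base = np.uint64(N_CLASS + 1)
    for j in range(window):
        key = (key * base + padded[j : j + len(aa_idx)]).astype(np.uint64)
    return _g_table(window, skew)[key.astype(np.int64)]


def smooth_tokens(tokens: np.ndarray) -> np.ndarray:
    """Majority vote over each 3-window (ties keep the centre token)."""
    if len(tokens) < 3:
        return tokens.copy()
    out = tokens.copy()
    left, right = tokens[:-2], tokens[2:]
    agree = left == right
    out[1:-1][agree] = left[agree]
    return out


def structure_tokens(
    aa_idx: np.ndarray, cfg: WorldConfig, rng: np.random.Generator
) -> np.ndarray:
    """Full token pipeline: windowed map, run smoothing, uniform noise."""
    tokens = smooth_tokens(window_map(aa_idx, cfg.window, cfg.skew))
    if cfg.noise_rate > 0:
        hit = rng.random(len(tokens)) < cfg.noise_rate
        tokens[hit] = rng.integers(0, N_TDI, size=int(hit.sum()))
    return tokens


def _mutate(proto: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = proto.copy()
    hit = rng.random(len(out)) < rate
    out[hit] = rng.integers(0, N_AA, size=int(hit.sum()))
    return out


def generate_world(cfg: WorldConfig) -> List[ProteinRecord]:
    """Generate the full synthetic proteome described by ``cfg``."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_proto, rng_assign, rng_seq, rng_noise, rng_plddt = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    n_folds, n_super, n_fam = cfg.hierarchy_shape
    max_len = cfg.length_range[1]
    r_sf, r_fam, r_clu, r_prot = cfg.mutation_rates

    # top-down prototype chain: fold -> superfamily -> family
    family_protos: List[np.ndarray] = []
    family_labels: List[HierarchyLabel] = []
    for f in range(n_folds):
        fold_proto = rng_proto.integers(0, N_AA, size=max_len)
        for s in range(n_super):
            super_proto = _mutate(fold_proto, r_sf, rng_proto)
            for m in range(n_fam):
                family_protos.append(_mutate(super_proto, r_fam, rng_proto))
                family_labels.append(
                    HierarchyLabel((f"F{f}", f"S{f}-{s}", f"M{f}-{s}-{m}"))
                )
    n_families = len(family_protos)

    # clusters nested inside families, each with its own prototype
    cluster_family = np.arange(cfg.n_clusters) % n_families
    cluster_protos = [
        _mutate(family_protos[fam], r_clu, rng_proto) for fam in cluster_family
    ]

    protein_cluster = rng_assign.permutation(
        np.arange(cfg.n_proteins) % cfg.n_clusters
    )
    lengths = rng_seq.integers(cfg.length_range[0], cfg.length_range[1] + 1, size=cfg.n_proteins)

    records: List[ProteinRecord] = []
    width = len(str(cfg.n_proteins))
    for i in range(cfg.n_proteins):
        clu = int(protein_cluster[i])
        fam = int(cluster_family[clu])
        L = int(lengths[i])
        aa_idx = _mutate(cluster_protos[clu][:L], r_prot, rng_seq)
        tdi_idx = structure_tokens(aa_idx, cfg, rng_noise)
        plddt = _draw_plddt(rng_plddt, cfg.low_quality_frac)
        records.append(
            ProteinRecord(
                id=f"P{i:0{width}d}",
                aa_seq="".join(AA_ALPHABET[j] for j in aa_idx),
                tdi_seq="".join(TDI_ALPHABET[j] for j in tdi_idx),
                plddt=plddt,
                cluster_id=f"C{clu:04d}",
                hierarchy=family_labels[fam],
            )
        )
    return records


def _draw_plddt(rng: np.random.Generator, low_frac: float) -> float:
    """Mixture of two Beta(2,2)-shaped bands: [40,70) low, [70,100] high."""
    if rng.random() < low_frac:
        return float(40.0 + 30.0 * rng.beta(2.0, 2.0))
    return float(70.0 + 30.0 * rng.beta(2.0, 2.0))


def recompute_structure_tokens(aa_seq: str, cfg: WorldConfig) -> str:
    """Deterministic part of the token pipeline (noise-free g + smoothing)."""
    aa_idx = np.fromiter((AA_ALPHABET.index(c) for c in aa_seq), dtype=np.int64)
    tokens = smooth_tokens(window_map(aa_idx, cfg.window, cfg.skew))
    return "".join(TDI_ALPHABET[j] for j in tokens)


# ---------------------------------------------------------------------------
# secondary-structure co-occurrence
# ---------------------------------------------------------------------------

SS3_STATES = "HEO"

_DSSP_TO_SS3 = {
    "G": "H", "H": "H", "I": "H",
    "B": "E", "E": "E",
    "-": "O", "T": "O", "S": "O",
}


def dssp8_to_ss3(ss8: str) -> str:
    """Collapse 8-state secondary structure to Helix / strand (E) / Other."""
    try:
        return "".join(_DSSP_TO_SS3[c] for c in ss8)
    except KeyError as e:
        raise ValueError(f"unknown 8-state code {e.args[0]!r}") from None


def ss3_cooccurrence(
    records: Sequence[ProteinRecord], ss3: Sequence[str]
) -> Tuple[np.ndarray, np.ndarray]:
    """Count how each structure token co-occurs with 3-state secondary structure.

    Returns ``(counts, proportions)``, both 20x3 over (token, {H,E,O});
    proportion rows sum to 1 where the token was observed and are 0 otherwise.
    """
    if len(records) != len(ss3):
        raise ValueError("need one secondary-structure string per record")
    counts = np.zeros((N_TDI, 3), dtype=np.int64)
    ss_index = {c: k for k, c in enumerate(SS3_STATES)}
    tdi_index = {c: k for k, c in enumerate(TDI_ALPHABET)}
    for rec, labels in zip(records, ss3):
        if rec.tdi_seq is None or len(rec.tdi_seq) != len(labels):
            raise ValueError(f"record {rec.id!r}: labels not aligned to structure tokens")
        for t, s in zip(rec.tdi_seq, labels):
            counts[tdi_index[t], ss_index[s]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    props = np.divide(counts, totals, out=np.zeros_like(counts, dtype=float), where=totals > 0)
    return counts, props


def token_frequencies(records: Sequence[ProteinRecord]) -> np.ndarray:
    """Empirical structure-token distribution over all residues."""
    counts = np.zeros(N_TDI, dtype=np.int64)
    tdi_index = {c: k for k, c in enumerate(TDI_ALPHABET)}
    for rec in records:
        if rec.tdi_seq:
            for t in rec.tdi_seq:
                counts[tdi_index[t]] += 1
    total = counts.sum()
    return counts / total if total else counts.astype(float)
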