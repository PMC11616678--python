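"""Dataset quality filters and cluster-aware train/val/test splitting.

Three filters remove, in order: (a) low-quality structures (pLDDT < 70),
(b) short proteins (length < 30), (c) proteins with highly repetitive
structure-token strings (more than 95% of residues assigned to a single
token). Thresholds are strict as printed: equality survives. Splitting
moves *whole clusters* into validation/test so no cluster ever straddles
splits, and each val/test cluster designates its highest-pLDDT member as
representative for the redundancy-free evaluation views.
"""

from __future__ import annotations

from collections import Counter, OrderedDict
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .records import ProteinRecord


@dataclass
class CurationConfig:
    min_plddt: float = 70.0
    min_length: int = 30
    max_single_token_frac: float = 0.95
    max_cluster_members: int = 20
    val_size: int = 0
    test_size: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_single_token_frac <= 1.0):
            raise ValueError("max_single_token_frac must lie in [0, 1]")
        if self.val_size < 0 or self.test_size < 0:
            raise ValueError("split sizes must be >= 0")


FILTER_RULES = ("low_plddt", "short", "repetitive")


def single_token_fraction(tdi_seq: str) -> float:
    if not tdi_seq:
        return 0.0
    return max(Counter(tdi_seq).values()) / len(tdi_seq)


def apply_filters(
    records: Sequence[ProteinRecord], cfg: CurationConfig
) -> Tuple[List[ProteinRecord], Dict[str, int]]:
    """Apply the three quality filters; count removals per first-failing rule."""
    kept: List[ProteinRecord] = []
    report = {rule: 0 for rule in FILTER_RULES}
    for rec in records:
        if rec.plddt is None:
            raise ValueError(f"record {rec.id!r} lacks a pLDDT score")
        if rec.tdi_seq is None:
            raise ValueError(f"record {rec.id!r} lacks a structure-token string")
        if rec.plddt < cfg.min_plddt:
            report["low_plddt"] += 1
        elif rec.length < cfg.min_length:
            report["short"] += 1
        elif single_token_fraction(rec.tdi_seq) > cfg.max_single_token_frac:
            report["repetitive"] += 1
        else:
            kept.append(rec)
    return kept, report


def cluster_split(
    records: Sequence[ProteinRecord], cfg: CurationConfig
) -> List[ProteinRecord]:
    """Assign whole clusters to val/test until the requested sizes accumulate.

    Clusters are drawn in seeded random order; a cluster's members all land
    in the same split. Remaining clusters go to train. Representatives (the
    highest-pLDDT member per val/test cluster) are exposed by
    :func:`representatives`.
    """
    clusters: "OrderedDict[str, List[ProteinRecord]]" = OrderedDict()
    for rec in records:
        if rec.cluster_id is None:
            raise ValueError(f"record {rec.id!r} lacks a cluster id")
        clusters.setdefault(rec.cluster_id, []).append(rec)

    rng = np.random.default_rng(cfg.seed)
    order = list(clusters)
    rng.shuffle(order)

    assignment: Dict[str, str] = {}
    n_val = n_test = 0
    idx = 0
    while n_val < cfg.val_size and idx < len(order):
        cid = order[idx]
        assignment[cid] = "val"
        n_val += len(clusters[cid])
        idx += 1
    while n_test < cfg.test_size and idx < len(order):
        cid = order[idx]
        assignment[cid] = "test"
        n_test += len(clusters[cid])
        idx += 1
    if n_val < cfg.val_size or n_test < cfg.test_size:
        raise ValueError(
            "not enough clusters to fill the requested validation/test sizes"
        )
    out = [
        rec.with_(split=assignment.get(rec.cluster_id, "train")) for rec in records
    ]
    return out


def representatives(records: Sequence[ProteinRecord], split: str) -> List[ProteinRecord]:
    """Redundancy-free view: the highest-pLDDT member of each cluster in ``split``."""
    best: "OrderedDict[str, ProteinRecord]" = OrderedDict()
    for rec in records:
        if rec.split != split:
            continue
        cur = best.get(rec.cluster_id)
        if cur is None or (rec.plddt or 0.0) > (cur.plddt or 0.0):
            best[rec.cluster_id] = rec
    return list(best.values())


def hamming_identity_distance(a: ProteinRecord, b: ProteinRecord) -> float:
    """1 - fraction of identical positions over the shorter sequence.

    Simple default dissimilarity for diversity capping; any callable
    ``(record, record) -> float`` may replace it.
    """
    n = min(len(a.aa_seq), len(b.aa_seq))
    if n == 0:
        return 1.0
    same = sum(x == y for x, y in zip(a.aa_seq[:n], b.aa_seq[:n]))
    return 1.0 - same / n


def cap_cluster(
    records_in_cluster: Sequence[ProteinRecord],
    k: int,
    distance: Optional[Callable[[ProteinRecord, ProteinRecord], float]] = None,
    representative: Optional[ProteinRecord] = None,
) -> List[ProteinRecord]:
    """Greedy max-min diversity selection of at most ``k`` cluster members.

    Starts from the representative (highest pLDDT unless given) and repeatedly
    adds the member whose minimum distance to the selected set is largest.
    Ties break towards the earlier record for determinism.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    members = list(records_in_cluster)
    if len(members) <= k:
        return members
    if distance is None:
        distance = hamming_identity_distance
    if representative is None:
        representative = max(members, key=lambda r: (r.plddt or 0.0))
    selected = [representative]
    remaining = [m for m in members if m is not representative]
    min_dist = {m.id: distance(m, representative) for m in remaining}
    while len(selected) < k and remaining:
        best = max(remaining, key=lambda m: min_dist[m.id])
        selected.append(best)
        remaining.remove(best)
        for m in remaining:
            d = distance(m, best)
            if d < min_dist[m.id]:
                min_dist[m.id] = d
    return selected


def curation_report(
    filter_report: Dict[str, int], records: Sequence[ProteinRecord]
) -> Dict[str, Dict[str, int]]:
    """JSON-friendly summary: removals per rule and record counts per split."""
    per_split = Counter(r.split for r in records)
    return {"removed": dict(filter_report), "splits": dict(per_split)}
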