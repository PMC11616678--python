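"""Independent alignment oracle: exhaustive enumeration of global alignments.

Every global alignment of an (n, m) pair is a monotone path of moves
D (align a_i with b_j), U (a_i against a gap), L (b_j against a gap).
Paths are enumerated once per shape and scored directly from their structure:
substitution scores over the D moves plus affine gap costs over maximal
same-type gap runs (open for the first residue, extend for the rest).
This never touches the dynamic-programming aligner it is used to check.
"""

from __future__ import annotations

from functools import lru_cache
from typing import List, Tuple

import numpy as np


@lru_cache(maxsize=None)
def enumerate_paths(n: int, m: int) -> Tuple[str, ...]:
    """All move strings from (0,0) to (n,m)."""
    if n == 0 and m == 0:
        return ("",)
    out: List[str] = []
    if n > 0 and m > 0:
        out.extend(p + "D" for p in enumerate_paths(n - 1, m - 1))
    if n > 0:
        out.extend(p + "U" for p in enumerate_paths(n - 1, m))
    if m > 0:
        out.extend(p + "L" for p in enumerate_paths(n, m - 1))
    return tuple(out)


def gap_cost(path: str, gap_open: int, gap_extend: int) -> int:
    cost = 0
    prev = "D"
    for move in path:
        if move == "D":
            prev = "D"
            continue
        cost += gap_extend if move == prev else gap_open
        prev = move
    return cost


@lru_cache(maxsize=None)
def _shape_tables(n: int, m: int, gap_open: int, gap_extend: int):
    """Flattened diagonal-cell indices + per-path gap costs for one shape."""
    paths = enumerate_paths(n, m)
    flat: List[int] = []
    bounds = [0]
    costs = np.empty(len(paths), dtype=np.int64)
    for k, path in enumerate(paths):
        i = j = 0
        for move in path:
            if move == "D":
                flat.append(i * m + j)
                i += 1
                j += 1
            elif move == "U":
                i += 1
            else:
                j += 1
        bounds.append(len(flat))
        costs[k] = gap_cost(path, gap_open, gap_extend)
    return np.asarray(flat, dtype=np.int64), np.asarray(bounds[:-1], dtype=np.int64), costs


def brute_force_score(a: str, b: str, mat) -> int:
    """Optimal global alignment score by scoring every alignment."""
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        gap_len = max(n, m)
        return 0 if gap_len == 0 else mat.gap_open + (gap_len - 1) * mat.gap_extend
    flat, starts, costs = _shape_tables(n, m, mat.gap_open, mat.gap_extend)
    cell = mat.scores[np.ix_(mat.encode(a), mat.encode(b))].reshape(-1)
    # trailing zero keeps every reduceat start index in bounds (a path may
    # start its — possibly empty — diagonal segment at the very end)
    values = np.append(cell[flat], 0)
    sums = np.add.reduceat(values, starts)
    empty = np.diff(np.append(starts, len(flat))) == 0
    sums[empty] = 0
    return int((sums + costs).max())
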