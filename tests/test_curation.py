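"""Quality filters (strict thresholds), cluster-aware splits, diversity capping."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pro3di.curation import (
    CurationConfig,
    apply_filters,
    cap_cluster,
    cluster_split,
    representatives,
    single_token_fraction,
)
from pro3di.records import ProteinRecord


def _rec(i, plddt=90.0, length=100, repeat_frac=0.0, cluster="C0"):
    n_rep = int(round(repeat_frac * length))
    tdi = "d" * n_rep + ("vpk" * length)[: length - n_rep]
    aa = "A" * length
    return ProteinRecord(
        id=f"r{i}", aa_seq=aa, tdi_seq=tdi, plddt=plddt, cluster_id=cluster
    )


class TestFilters:
    def test_low_plddt_removed_strictly_below_threshold(self):
        kept, report = apply_filters([_rec(0, plddt=69.9)], CurationConfig())
        assert kept == [] and report["low_plddt"] == 1

    def test_boundary_plddt_survives(self):
        kept, _ = apply_filters([_rec(0, plddt=70.0)], CurationConfig())
        assert len(kept) == 1

    def test_short_removed_boundary_survives(self):
        kept, report = apply_filters(
            [_rec(0, length=29), _rec(1, length=30)], CurationConfig()
        )
        assert [r.id for r in kept] == ["r1"] and report["short"] == 1

    def test_repetitive_strictly_above_fraction_removed(self):
        removed = _rec(0, repeat_frac=0.96)
        boundary = _rec(1, repeat_frac=0.95)
        assert single_token_fraction(removed.tdi_seq) > 0.95
        assert single_token_fraction(boundary.tdi_seq) == pytest.approx(0.95)
        kept, report = apply_filters([removed, boundary], CurationConfig())
        assert [r.id for r in kept] == ["r1"] and report["repetitive"] == 1

    def test_multiply_failing_record_counted_under_first_rule(self):
        bad = _rec(0, plddt=10.0, length=10)
        _, report = apply_filters([bad], CurationConfig())
        assert report == {"low_plddt": 1, "short": 0, "repetitive": 0}

    def test_missing_plddt_raises(self):
        rec = ProteinRecord(id="x", aa_seq="A" * 40, tdi_seq="v" * 40)
        with pytest.raises(ValueError, match="pLDDT"):
            apply_filters([rec], CurationConfig())

    @settings(derandomize=True, max_examples=30)
    @given(
        min_plddt=st.floats(min_value=0, max_value=100),
        min_length=st.integers(min_value=0, max_value=120),
    )
    def test_pass_rate_monotone_in_thresholds(self, min_plddt, min_length):
        rng = np.random.default_rng(0)
        records = [
            _rec(i, plddt=float(rng.uniform(40, 100)), length=int(rng.integers(10, 120)))
            for i in range(40)
        ]
        base = CurationConfig()
        kept_loose, _ = apply_filters(records, base)
        cfg = CurationConfig(
            min_plddt=max(min_plddt, base.min_plddt),
            min_length=max(min_length, base.min_length),
        )
        kept_tight, _ = apply_filters(records, cfg)
        assert len(kept_tight) <= len(kept_loose)


def _clustered_records(sizes, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    i = 0
    for c, size in enumerate(sizes):
        for _ in range(size):
            out.append(
                ProteinRecord(
                    id=f"p{i}",
                    aa_seq="A" * 40,
                    tdi_seq="v" * 40,
                    plddt=float(rng.uniform(70, 100)),
                    cluster_id=f"C{c}",
                )
            )
            i += 1
    return out


class TestClusterSplit:
    def test_no_cluster_straddles_splits(self):
        records = _clustered_records([5, 3, 2, 7, 4])
        out = cluster_split(records, CurationConfig(val_size=4, test_size=4, seed=1))
        per_cluster = {}
        for r in out:
            per_cluster.setdefault(r.cluster_id, set()).add(r.split)
        assert all(len(s) == 1 for s in per_cluster.values())

    def test_three_clusters_one_each_for_val_and_test(self):
        # clusters of sizes 5/3/2 with val_size=test_size=2: the first drawn
        # cluster fills val, the second fills test, the third trains
        records = _clustered_records([5, 3, 2])
        out = cluster_split(records, CurationConfig(val_size=2, test_size=2, seed=0))
        val_clusters = {r.cluster_id for r in out if r.split == "val"}
        test_clusters = {r.cluster_id for r in out if r.split == "test"}
        assert len(val_clusters) == 1 and len(test_clusters) == 1
        assert not val_clusters & test_clusters
        assert len(representatives(out, "val")) == 1
        assert len(representatives(out, "test")) == 1

    def test_zero_sizes_all_train(self):
        records = _clustered_records([3, 2])
        out = cluster_split(records, CurationConfig(val_size=0, test_size=0))
        assert all(r.split == "train" for r in out)

    def test_not_enough_clusters_raises(self):
        records = _clustered_records([2])
        with pytest.raises(ValueError, match="clusters"):
            cluster_split(records, CurationConfig(val_size=2, test_size=2))

    def test_deterministic_given_seed(self):
        records = _clustered_records([5, 3, 2, 7, 4])
        cfg = CurationConfig(val_size=4, test_size=4, seed=3)
        a = [r.split for r in cluster_split(records, cfg)]
        b = [r.split for r in cluster_split(records, cfg)]
        assert a == b

    def test_representative_is_highest_plddt_member(self):
        records = _clustered_records([6], seed=5)
        out = cluster_split(records, CurationConfig(val_size=1, test_size=0, seed=0))
        rep = representatives(out, "val")
        assert len(rep) == 1
        assert rep[0].plddt == max(r.plddt for r in out)


class Test1DCapCluster:
    """cap_cluster on records with a synthetic 1-D coordinate distance."""

    @staticmethod
    def _points(values):
        recs = [
            ProteinRecord(id=f"x{v}", aa_seq="A" * 10, tdi_seq="v" * 10, plddt=50.0 + i)
            for i, v in enumerate(values)
        ]
        coords = {r.id: v for r, v in zip(recs, values)}
        return recs, lambda a, b: abs(coords[a.id] - coords[b.id])

    def test_small_cluster_unchanged(self):
        recs, dist = self._points([0, 1, 2])
        assert cap_cluster(recs, 5, distance=dist) == recs

    def test_greedy_maxmin_matches_bruteforce(self):
        values = [0, 1, 2, 10]
        recs, dist = self._points(values)
        chosen = cap_cluster(recs, 3, distance=dist, representative=recs[0])
        assert {r.id for r in chosen} == {"x0", "x10", "x2"}
        # brute force over all 3-subsets containing the representative
        def min_pair(subset):
            return min(abs(a - b) for a, b in itertools.combinations(subset, 2))

        best = max(
            (s for s in itertools.combinations(values, 3) if 0 in s), key=min_pair
        )
        assert {f"x{v}" for v in best} == {r.id for r in chosen}

    def test_k1_returns_representative_only(self):
        recs, dist = self._points([0, 1, 2, 3])
        chosen = cap_cluster(recs, 1, distance=dist, representative=recs[2])
        assert chosen == [recs[2]]

    def test_default_representative_is_highest_plddt(self):
        recs, dist = self._points([0, 5, 9])
        chosen = cap_cluster(recs, 1, distance=dist)
        assert chosen[0].plddt == max(r.plddt for r in recs)
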