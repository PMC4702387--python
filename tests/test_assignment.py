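import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from corebin import assignment
from corebin.assignment import FilterParams
from corebin.model import Cluster, ClusterLabel, Hit, HitList


def _hit(taxon, score, query="r1"):
    return Hit(query_id=query, subject_id=f"s{taxon}", taxon=taxon, bit_score=score)


def _hitlist(read_id, taxa, score=80.0):
    return HitList(read_id=read_id, hits=[_hit(t, score, read_id) for t in taxa])


class TestDedupeHits:
    def test_max_score_kept_per_taxon(self):
        hl = assignment.dedupe_hits([_hit(7, 40.0), _hit(7, 60.0)])
        assert len(hl) == 1 and hl.hits[0].bit_score == 60.0

    def test_distinct_list_unchanged(self):
        raw = [_hit(1, 50.0), _hit(2, 60.0)]
        assert assignment.dedupe_hits(raw).hits == raw

    def test_empty_list(self):
        assert assignment.dedupe_hits([]).hits == []

    def test_mixed_queries_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            assignment.dedupe_hits([_hit(1, 50.0, "r1"), _hit(2, 50.0, "r2")])


class TestReadLevelFilter:
    def test_all_below_min_score(self):
        hl = HitList("r1", [_hit(1, 10.0), _hit(2, 20.0)])
        assert assignment.read_level_filter(hl, s_min=35, p_top=10).hits == []

    def test_top_percent_cutoff(self):
        hl = HitList("r1", [_hit(1, 100.0), _hit(2, 95.0), _hit(3, 80.0)])
        out = assignment.read_level_filter(hl, s_min=35, p_top=10)
        assert {h.taxon for h in out.hits} == {1, 2}  # cutoff 90

    def test_p_top_100_keeps_everything_above_floor(self):
        hl = HitList("r1", [_hit(1, 100.0), _hit(2, 36.0), _hit(3, 10.0)])
        out = assignment.read_level_filter(hl, s_min=35, p_top=100)
        assert {h.taxon for h in out.hits} == {1, 2}


class TestClusterLevelFilter:
    def test_worked_majority_example(self):
        """Five core hit lists, 60 % threshold = 3 lists: only the taxon seen
        in four of them survives."""
        G1, G2, G3, G4 = 101, 102, 103, 104
        L = [
            _hitlist("r1", [G1, G2, G3]),
            _hitlist("r2", [G1, G4]),
            _hitlist("r3", [G2, G3]),
            _hitlist("r4", [G2, G4]),
            _hitlist("r5", [G2]),
        ]
        out = assignment.cluster_level_filter(L, o_max=60)
        surviving = set().union(*(hl.taxa() for hl in out))
        assert surviving == {G2}

    def test_single_list_always_retained(self):
        L = [_hitlist("r1", [1, 2, 3])]
        out = assignment.cluster_level_filter(L, o_max=100)
        assert out[0].taxa() == {1, 2, 3}

    def test_halving_rescues_all_empty(self):
        L = [_hitlist(f"r{i}", [i]) for i in range(1, 5)]
        out = assignment.cluster_level_filter(L, o_max=50)
        # threshold 2 empties everything; halved to 25 % -> threshold 1
        assert [hl.taxa() for hl in out] == [{1}, {2}, {3}, {4}]

    def test_halving_happens_only_once(self):
        L = [_hitlist(f"r{i}", [i]) for i in range(1, 11)]
        out = assignment.cluster_level_filter(L, o_max=100)
        # threshold 10 -> empty; halved threshold 5 -> still empty; stays empty
        assert all(not hl.hits for hl in out)

    def test_matches_bruteforce_retention_on_random_lists(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n_lists = int(rng.integers(1, 11))
            L = [
                _hitlist(
                    f"r{j}",
                    list(rng.choice(10, size=rng.integers(0, 6), replace=False)),
                )
                for j in range(n_lists)
            ]
            o_max = float(rng.uniform(5, 100))
            out = assignment.cluster_level_filter(L, o_max)
            # brute-force: count lists containing t at the effective threshold
            def retained_at(o):
                keep = set()
                for t in set().union(*(hl.taxa() for hl in L)):
                    f_t = sum(1 for hl in L if t in hl.taxa())
                    if f_t >= (o / 100) * len(L):
                        keep.add(t)
                return keep
            keep = retained_at(o_max)
            if any(hl.taxa() for hl in L) and not any(
                hl.taxa() & keep for hl in L
            ):
                keep = retained_at(o_max / 2)
            for before, after in zip(L, out):
                assert after.taxa() == before.taxa() & keep

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        scores=st.lists(
            st.tuples(st.integers(1, 6), st.floats(0, 120, allow_nan=False)),
            min_size=1,
            max_size=8,
        ),
        s_lo=st.floats(0, 60),
        s_hi=st.floats(0, 60),
        p_lo=st.floats(0, 100),
        p_hi=st.floats(0, 100),
    )
    def test_read_filter_monotone_in_thresholds(self, scores, s_lo, s_hi, p_lo, p_hi):
        """Raising s_min or lowering p_top never adds a retained hit."""
        hl = assignment.dedupe_hits(
            [_hit(t, s) for t, s in scores], read_id="r1"
        )
        s_min, s_max = min(s_lo, s_hi), max(s_lo, s_hi)
        p_min, p_max = min(p_lo, p_hi), max(p_lo, p_hi)
        strict = assignment.read_level_filter(hl, s_max, p_min)
        loose = assignment.read_level_filter(hl, s_min, p_max)
        assert strict.taxa() <= loose.taxa()

    def test_cluster_filter_monotone_in_o_max_pre_halving(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            L = [
                _hitlist(f"r{j}", list(rng.choice(8, size=rng.integers(1, 5), replace=False)))
                for j in range(int(rng.integers(1, 8)))
            ]
            o1, o2 = sorted(rng.uniform(1, 100, size=2))
            lo = assignment._retain(L, o1)
            hi = assignment._retain(L, o2)
            for a, b in zip(hi, lo):
                assert a.taxa() <= b.taxa()

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(29)
        L = [
            _hitlist(f"r{j}", list(rng.choice(8, size=3, replace=False)))
            for j in range(5)
        ]
        out = assignment._retain(L, 40.0)
        for before, after in zip(L, out):
            assert after.taxa() <= before.taxa()

    def test_empty_L_rejected(self):
        with pytest.raises(ValueError):
            assignment.cluster_level_filter([], 50)


class TestLabelCluster:
    def test_no_hits_gives_no_label(self, lineage_tree):
        label = assignment.label_cluster(0, [], FilterParams(), lineage_tree)
        assert label.taxid is None

    def test_unanimous_taxon_labels_directly(self, lineage_tree):
        L = [_hitlist("r1", [6]), _hitlist("r2", [6])]
        label = assignment.label_cluster(0, L, FilterParams(), lineage_tree)
        assert label.taxid == 6

    def test_sibling_species_label_at_genus(self, lineage_tree):
        # both survive the 50 % occurrence threshold -> LCA = genus
        L = [_hitlist("r1", [6, 7]), _hitlist("r2", [6, 7])]
        label = assignment.label_cluster(0, L, FilterParams(), lineage_tree)
        assert label.taxid == 5

    def test_label_is_ancestor_of_every_survivor(self, lineage_tree):
        L = [_hitlist("r1", [6, 9]), _hitlist("r2", [6, 9])]
        label = assignment.label_cluster(0, L, FilterParams(), lineage_tree)
        assert label.taxid is not None
        for t in (6, 9):
            assert label.taxid in lineage_tree.ancestors(t)


class TestPostProcess:
    def _cluster(self, cid, rids):
        return Cluster(cluster_id=cid, group_ids=[cid], read_ids=set(rids))

    def test_same_label_clusters_merge_to_smallest_id(self, lineage_tree):
        clusters = [self._cluster(0, ["r1"]), self._cluster(1, ["r2"])]
        labels = [ClusterLabel(0, 6), ClusterLabel(1, 6)]
        out = assignment.post_process(labels, clusters, lineage_tree)
        assert {a.cluster_id for a in out} == {0}
        assert all(a.taxid == 6 for a in out)

    def test_root_label_means_unassigned(self, lineage_tree):
        clusters = [self._cluster(0, ["r1", "r2"])]
        labels = [ClusterLabel(0, 1)]
        out = assignment.post_process(labels, clusters, lineage_tree)
        assert all(a.taxid is None for a in out)

    def test_mixed_labels_counted_by_rule(self, lineage_tree):
        clusters = [
            self._cluster(0, ["r1", "r2"]),
            self._cluster(1, ["r3", "r4"]),
            self._cluster(2, ["r5", "r6"]),
        ]
        labels = [ClusterLabel(0, 6), ClusterLabel(1, None), ClusterLabel(2, 1)]
        out = assignment.post_process(labels, clusters, lineage_tree)
        assert sum(1 for a in out if a.taxid is not None) == 2
        assert sum(1 for a in out if a.taxid is None) == 4

    def test_every_read_appears_once_sorted(self, lineage_tree):
        clusters = [self._cluster(0, ["r2", "r1"]), self._cluster(1, ["r3"])]
        labels = [ClusterLabel(0, 6), ClusterLabel(1, 7)]
        out = assignment.post_process(labels, clusters, lineage_tree)
        assert [a.read_id for a in out] == ["r1", "r2", "r3"]


class TestFilterParams:
    @pytest.mark.parametrize(
        "kwargs", [{"s_min": -1}, {"p_top": 101}, {"o_max": 0}, {"o_max": 101}]
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FilterParams(**kwargs)
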