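"""Diversity filter stages: greedy identity filter, qsc, farthest-point
selection, and the bucketed diversity filter's isolation properties."""

import numpy as np
import pytest

from conftest import brute_force_max_identity
from foldprep.filtering import (
    FilterParams,
    bucketed_diff_filter,
    max_seq_id_filter,
    maxdiv_select,
    qsc_filter,
    qsc_scores,
    stage1_cluster_filter,
)
from foldprep.fixtures import make_cluster_rows, make_msa
from foldprep.msa import AlignedSequence, Msa, query_identity


def row(header, seq):
    return AlignedSequence(header, seq)


class TestMaxSeqIdFilter:
    def test_identical_pair_collapses(self):
        rows = [row("a", "ACDEFGHIKL"), row("b", "ACDEFGHIKL")]
        assert [r.header for r in max_seq_id_filter(rows, 0.95)] == ["a"]

    def test_single_row_kept(self):
        rows = [row("a", "ACDE")]
        assert max_seq_id_filter(rows, 0.95) == rows

    def test_priority_order_wins(self):
        # rows a,b are 96% identical; c is distinct -> greedy keeps {a, c}
        base = "A" * 25
        rows = [
            row("a", base),
            row("b", base[:-1] + "C"),       # 24/25 = 0.96 identity to a
            row("c", "W" * 25),
        ]
        kept = max_seq_id_filter(rows, 0.95)
        assert [r.header for r in kept] == ["a", "c"]

    @pytest.mark.parametrize("threshold", [0.3, 0.6, 0.95])
    @pytest.mark.parametrize("seed", [0, 3])
    def test_against_brute_force_oracle(self, threshold, seed):
        """Greedy output never contains a pair above the threshold, and every
        dropped row conflicts with some kept row (checked by brute force)."""
        msa = make_msa(50, 30, [0.3, 0.5, 0.7, 0.9, 1.0], seed=seed)
        rows = msa.rows[1:]
        kept = max_seq_id_filter(rows, threshold)
        assert brute_force_max_identity(kept) <= threshold
        kept_ids = {r.header for r in kept}
        from foldprep.msa import pairwise_identity

        for r in rows:
            if r.header not in kept_ids:
                assert any(
                    pairwise_identity(r, k) > threshold
                    for k in kept
                ), f"row {r.header} was dropped without a conflicting kept row"


class TestQscFilter:
    def test_below_min_enable_passthrough(self):
        q = row("q", "ACDEFGHIKL" * 3)
        rows = [row(f"h{i}", "W" * 30) for i in range(99)]
        assert qsc_filter(rows, q, min_qsc=0.8, min_enable=100) == rows

    def test_query_self_copies_all_kept(self):
        q = row("q", "ACDEFGHIKLMNPQRSTVWY")
        rows = [row(f"h{i}", q.aligned) for i in range(100)]
        scores = qsc_scores(rows, q)
        assert (scores >= 0.8).all()  # self-score per column >= 1.0 on this scale
        assert len(qsc_filter(rows, q, 0.8, 100)) == 100

    def test_poor_rows_dropped_once_enabled(self):
        q = row("q", "ACDEFGHIKL" * 3)
        good = [row(f"g{i}", q.aligned) for i in range(60)]
        bad = [row(f"b{i}", "-" * 30) for i in range(60)]
        kept = qsc_filter(good + bad, q, 0.8, 100)
        assert [r.header for r in kept] == [r.header for r in good]

    def test_zero_threshold_disables(self):
        q = row("q", "ACDEFGHIKL" * 3)
        rows = [row(f"h{i}", "-" * 30) for i in range(150)]
        assert qsc_filter(rows, q, min_qsc=0.0) == rows

    def test_empty_input(self):
        q = row("q", "ACDE")
        assert qsc_filter([], q) == []


class TestMaxdivSelect:
    def test_k_at_least_n_returns_input_order(self, small_msa):
        rows = small_msa.rows[1:]
        assert maxdiv_select(rows, len(rows) + 5) == rows

    def test_cluster_of_50_reduced_to_10(self):
        msa = make_msa(50, 40, [0.6], seed=4)
        assert len(maxdiv_select(msa.rows[1:], 10)) == 10

    def test_hand_traced_farthest_point(self):
        # identities: (1,2)=0.9, (1,3)=0.2, (2,3)=0.2; seed=row1, farthest=row3
        idmat = np.array([
            [1.0, 0.9, 0.2],
            [0.9, 1.0, 0.2],
            [0.2, 0.2, 1.0],
        ])
        rows = [row("r1", "AAAA"), row("r2", "AAAA"), row("r3", "AAAA")]
        kept = maxdiv_select(rows, 2, identity_matrix=idmat)
        assert [r.header for r in kept] == ["r1", "r3"]

    def test_selection_preserves_input_order(self):
        msa = make_msa(30, 40, [0.2, 0.5, 0.8], seed=5)
        rows = msa.rows[1:]
        kept = maxdiv_select(rows, 7)
        positions = [rows.index(r) for r in kept]
        assert positions == sorted(positions)


class TestBucketedDiffFilter:
    def small_params(self, **kw):
        defaults = dict(diff=5, filter_min_enable=10)
        defaults.update(kw)
        return FilterParams(**defaults)

    def test_query_only_msa(self):
        msa = make_msa(0, 30, [0.5], seed=0)
        out = bucketed_diff_filter(msa)
        assert len(out) == 1

    def test_sparse_bucket_passes_through(self):
        msa = make_msa(9, 40, [0.5], seed=1)  # below min_enable=10
        out = bucketed_diff_filter(msa, self.small_params())
        assert len(out) == 10

    def test_saturated_bucket_capped_at_diff(self):
        msa = make_msa(40, 40, [0.5], seed=2)
        out = bucketed_diff_filter(msa, self.small_params())
        assert len(out) == 6  # query + diff

    def test_query_always_first(self, small_msa):
        out = bucketed_diff_filter(small_msa, self.small_params())
        assert out.rows[0] is small_msa.query

    def test_idempotent(self):
        msa = make_msa(200, 40, [0.1, 0.3, 0.5, 0.7, 0.9], seed=3)
        p = self.small_params()
        once = bucketed_diff_filter(msa, p)
        twice = bucketed_diff_filter(once, p)
        assert [r.header for r in twice.rows] == [r.header for r in once.rows]

    def test_bucket_isolation(self):
        """Deleting one bucket's rows never changes what other buckets keep."""
        p = self.small_params()
        msa = make_msa(120, 40, [0.1, 0.5, 0.9], seed=6)
        full = bucketed_diff_filter(msa, p)
        # remove every row in the middle bucket (identity in (0.4, 0.6])
        kept_rows = [
            r for r in msa.rows[1:]
            if not (0.4 < query_identity(r, msa.query) <= 0.6)
        ]
        reduced = bucketed_diff_filter(Msa([msa.query] + kept_rows), p)
        survivors_full = {
            r.header for r in full.rows[1:]
            if not (0.4 < query_identity(r, msa.query) <= 0.6)
        }
        survivors_reduced = {r.header for r in reduced.rows[1:]}
        assert survivors_full == survivors_reduced

    def test_output_preserves_relative_order(self):
        msa = make_msa(60, 40, [0.5], seed=8)
        out = bucketed_diff_filter(msa, self.small_params())
        positions = [msa.rows.index(r) for r in out.rows]
        assert positions == sorted(positions)

    def test_bucket_boundaries_as_printed(self):
        p = FilterParams()
        assert p.bucket_of(0.0) == 0
        assert p.bucket_of(0.2) == 0   # first bucket closed [0.0, 0.2]
        assert p.bucket_of(0.2000001) == 1
        assert p.bucket_of(0.8) == 3
        assert p.bucket_of(1.0) == 4


class TestStage1ClusterFilter:
    def test_duplicates_collapse_within_cluster(self):
        c = [row("a", "ACDEFGHIKL" * 2), row("b", "ACDEFGHIKL" * 2)]
        assert len(stage1_cluster_filter([c])) == 1

    def test_per_cluster_independence(self):
        seq = "ACDEFGHIKL" * 2
        out = stage1_cluster_filter([[row("a", seq)], [row("b", seq)]])
        assert [r.header for r in out] == ["a", "b"]

    def test_singleton_cluster_unchanged(self):
        c = [row("a", "ACDE")]
        assert stage1_cluster_filter([c]) == c

    def test_near_duplicate_groups_respect_threshold(self):
        rows = make_cluster_rows(60, 100, 6, within_group_mut=2, seed=11)
        kept = stage1_cluster_filter([rows])
        assert brute_force_max_identity(kept) <= 0.95
        assert len(kept) < len(rows)
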