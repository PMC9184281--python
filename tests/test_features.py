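"""Complex MSA layouts, residue-index chain breaks, positional-encoding
bins, MSA subsampling and fixed-size padding."""

import numpy as np
import pytest

from foldprep.features import (
    ComplexSpec,
    FeatureSet,
    RESIDUE_INDEX_PAD,
    assemble_heterooligomer,
    assemble_homooligomer,
    build_residue_index,
    make_fixed_size,
    relative_position_bins,
    subsample_msa,
)
from foldprep.fixtures import make_msa, make_species_hits
from foldprep.msa import GAP_CODE, AlignedSequence, Msa, encode_rows
from foldprep.pairing import pair_by_species


class TestHomooligomer:
    def test_single_copy_is_identity(self, small_msa):
        assert assemble_homooligomer(small_msa, 1) is small_msa

    def test_dimensional_arithmetic(self):
        msa = make_msa(2, 10, [0.5], seed=0)  # query + 2 hits
        out = assemble_homooligomer(msa, 2)
        assert len(out) == 5  # 1 + copies * (rows - 1)
        assert out.query_length == 20

    def test_rows_occupy_one_block_each(self):
        msa = make_msa(3, 8, [0.6], seed=1)
        out = assemble_homooligomer(msa, 3)
        L = 8
        for row in out.rows[1:]:
            s = row.match_string
            blocks_with_residues = [
                any(c != "-" for c in s[k * L:(k + 1) * L]) for k in range(3)
            ]
            assert sum(blocks_with_residues) == 1

    def test_per_block_column_content_conserved(self):
        """Copying conserves content: residue counts per column within each
        block equal the single-copy MSA's counts."""
        msa = make_msa(6, 12, [0.3, 0.7], seed=2)
        copies = 2
        out = assemble_homooligomer(msa, copies)
        single = encode_rows(msa.rows[1:])
        assembled = encode_rows(out.rows[1:])
        L = msa.query_length
        for k in range(copies):
            block = assembled[:, k * L:(k + 1) * L]
            for col in range(L):
                a = np.sort(block[:, col][block[:, col] != GAP_CODE])
                b = np.sort(single[:, col][single[:, col] != GAP_CODE])
                assert np.array_equal(a, b)

    def test_invalid_copies(self, small_msa):
        with pytest.raises(ValueError):
            assemble_homooligomer(small_msa, 0)


class TestHeterooligomer:
    def chains(self):
        return make_msa(2, 10, [0.5], seed=3), make_msa(3, 6, [0.5], seed=4)

    def paired_block(self):
        tables = make_species_hits(2, [
            {"taxid": 1, "chains": {0: [{"evalue": 1e-6}], 1: [{"evalue": 1e-6}]}},
        ], qlen=10)
        # second chain is 6 long; rebuild its table with matching qlen
        tables2 = make_species_hits(2, [
            {"taxid": 1, "chains": {0: [{"evalue": 1e-6}], 1: [{"evalue": 1e-6}]}},
        ], qlen=6)
        return pair_by_species([tables[0], tables2[1]])

    def test_row_count_arithmetic(self):
        a, b = self.chains()  # 2 and 3 non-query rows
        paired = self.paired_block()
        out = assemble_heterooligomer(paired, [a, b])
        assert len(out) == 1 + 1 + 5

    def test_zero_paired_blocks_pure_block_diagonal(self):
        a, b = self.chains()
        out = assemble_heterooligomer([], [a, b])
        assert len(out) == 6
        for row in out.rows[1:]:
            s = row.match_string
            in_a = any(c != "-" for c in s[:10])
            in_b = any(c != "-" for c in s[10:])
            assert in_a != in_b  # exactly one block occupied

    def test_paired_rows_span_all_chains(self):
        a, b = self.chains()
        out = assemble_heterooligomer(self.paired_block(), [a, b])
        paired_row = out.rows[1].match_string
        assert any(c != "-" for c in paired_row[:10])
        assert any(c != "-" for c in paired_row[10:])

    def test_query_is_concatenation(self):
        a, b = self.chains()
        out = assemble_heterooligomer([], [a, b])
        assert out.rows[0].aligned == a.query.aligned + b.query.aligned

    def test_chain_length_mismatch_rejected(self):
        a, b = self.chains()
        bad = self.paired_block()
        bad[0].rows[1] = AlignedSequence("short", "ACDE")
        with pytest.raises(ValueError):
            assemble_heterooligomer(bad, [a, b])


class TestResidueIndex:
    def test_single_chain(self):
        assert build_residue_index([4]).tolist() == [0, 1, 2, 3]

    def test_two_chains_with_gap(self):
        assert build_residue_index([3, 3], 200).tolist() == [0, 1, 2, 203, 204, 205]

    def test_gap_at_cap_rejected(self):
        with pytest.raises(ValueError, match="32"):
            build_residue_index([3, 3], 32)

    def test_strictly_increasing_within_chains(self):
        ri = build_residue_index([5, 7, 3], 100)
        assert (np.diff(ri) > 0).all()


class TestRelativePositionBins:
    def test_diagonal_is_cap(self):
        bins = relative_position_bins(np.arange(10), cap=32)
        assert (np.diag(bins) == 32).all()

    def test_large_separations_share_bin(self):
        ri = np.array([0, 32, 10_000])
        bins = relative_position_bins(ri, cap=32)
        assert bins[0, 1] == bins[0, 2]

    def test_clipping_onset_at_cap(self):
        """Sweeping separations 1..100, bins become constant from 32 on."""
        seps = np.arange(1, 101)
        ri = np.concatenate([[0], seps])
        bins = relative_position_bins(ri, cap=32)[0, 1:]
        changes = np.flatnonzero(np.diff(bins) != 0)
        onset = seps[changes[-1] + 1]
        assert onset == 32

    def test_reflection_symmetry(self):
        ri = build_residue_index([4, 4], 200)
        bins = relative_position_bins(ri, cap=32)
        assert np.array_equal(bins + bins.T, np.full_like(bins, 64))

    def test_cross_chain_bins_are_extreme(self):
        ri = build_residue_index([5, 5], 200)
        bins = relative_position_bins(ri, cap=32)
        cross = bins[:5, 5:]
        assert set(np.unique(cross)) <= {0, 64}


class TestSubsample:
    def test_small_msa_all_cluster_rows(self):
        cluster, extra = subsample_msa(100, seed=0)
        assert len(cluster) == 100
        assert extra == []

    def test_caps_respected(self):
        cluster, extra = subsample_msa(5000, seed=1)
        assert len(cluster) == 512
        assert len(extra) == 1024
        assert not set(cluster) & set(extra)

    def test_query_always_cluster_row(self):
        for seed in range(5):
            cluster, _ = subsample_msa(2000, seed=seed)
            assert cluster[0] == 0

    def test_seed_reproducibility_and_variation(self):
        a = subsample_msa(3000, seed=42)
        b = subsample_msa(3000, seed=42)
        c = subsample_msa(3000, seed=43)
        assert a == b
        assert a != c

    def test_accepts_msa_object(self, small_msa):
        cluster, extra = subsample_msa(small_msa, max_clusters=10, max_extra=5, seed=0)
        assert len(cluster) == 10
        assert len(extra) == 5


class TestMakeFixedSize:
    def feature_set(self, length=100, rows=4):
        msa = make_msa(rows - 1, length, [0.5], seed=0)
        return FeatureSet.from_msa(msa)

    def test_ten_percent_padding(self):
        fs = make_fixed_size(self.feature_set(100), 0.1)
        assert fs.padded_length == 110
        assert fs.msa_matrix.shape[1] == 110

    def test_zero_padding(self):
        fs = make_fixed_size(self.feature_set(100), 0.0)
        assert fs.padded_length == 100

    def test_padded_columns_are_gap_and_sentinel(self):
        fs = make_fixed_size(self.feature_set(50), 0.1)
        assert (fs.msa_matrix[:, 50:] == GAP_CODE).all()
        assert (fs.residue_index[50:] == RESIDUE_INDEX_PAD).all()

    def test_json_round_trip(self):
        fs = make_fixed_size(self.feature_set(30), 0.1)
        back = FeatureSet.from_json(fs.to_json())
        assert np.array_equal(back.msa_matrix, fs.msa_matrix)
        assert np.array_equal(back.residue_index, fs.residue_index)
        assert back.chain_partition == fs.chain_partition


class TestComplexSpec:
    def test_chain_lengths_expand_copies(self):
        spec = ComplexSpec([("ACDE", 2), ("FG", 1)])
        assert spec.chain_lengths == [4, 4, 2]

    def test_invalid_copy_count(self):
        with pytest.raises(ValueError):
            ComplexSpec([("ACDE", 0)])
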