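"""Species and genome-distance pairing of per-chain hit tables."""

import itertools

import pytest

from foldprep.fixtures import make_species_hits
from foldprep.pairing import (
    accession_ordinal,
    pair_by_genome_distance,
    pair_by_species,
)


def layout_entry(taxid, chain_hits):
    return {"taxid": taxid, "chains": chain_hits}


class TestPairBySpecies:
    def test_best_hit_per_chain_selected(self):
        tables = make_species_hits(2, [
            layout_entry(9606, {
                0: [{"evalue": 1e-3, "target_id": "a_bad"},
                    {"evalue": 1e-6, "target_id": "a_good"}],
                1: [{"evalue": 1e-2, "target_id": "b_bad"},
                    {"evalue": 1e-5, "target_id": "b_good"}],
            }),
        ])
        blocks = pair_by_species(tables)
        assert len(blocks) == 1
        assert [r.identifier for r in blocks[0].rows] == ["a_good", "b_good"]

    def test_low_coverage_excludes_species(self):
        tables = make_species_hits(2, [
            layout_entry(9606, {
                0: [{"evalue": 1e-6}],
                1: [{"evalue": 1e-6, "coverage": 0.49}],
            }),
        ])
        assert pair_by_species(tables) == []

    def test_coverage_exactly_half_is_kept(self):
        tables = make_species_hits(2, [
            layout_entry(9606, {0: [{"evalue": 1e-6}],
                                1: [{"evalue": 1e-6, "coverage": 0.5}]}),
        ])
        assert len(pair_by_species(tables)) == 1

    def test_disjoint_species_sets_yield_nothing(self):
        tables = make_species_hits(2, [
            layout_entry(9606, {0: [{"evalue": 1e-6}]}),
            layout_entry(10090, {1: [{"evalue": 1e-6}]}),
        ])
        assert pair_by_species(tables) == []

    def test_blocks_sorted_by_combined_evalue(self):
        tables = make_species_hits(2, [
            layout_entry(1, {0: [{"evalue": 1e-2}], 1: [{"evalue": 1e-2}]}),
            layout_entry(2, {0: [{"evalue": 1e-8}], 1: [{"evalue": 1e-8}]}),
        ])
        blocks = pair_by_species(tables)
        assert [b.species_taxid for b in blocks] == [2, 1]

    def test_one_block_per_species_with_full_chain_rows(self):
        tables = make_species_hits(3, [
            layout_entry(1, {0: [{}, {}], 1: [{}], 2: [{}, {}, {}]}),
            layout_entry(2, {0: [{}], 1: [{}], 2: [{}]}),
        ])
        blocks = pair_by_species(tables)
        assert len(blocks) == 2
        assert all(len(b.rows) == 3 for b in blocks)
        assert len({b.species_taxid for b in blocks}) == 2

    def test_removing_non_selected_hit_changes_nothing(self):
        full = make_species_hits(2, [
            layout_entry(9606, {
                0: [{"evalue": 1e-6, "target_id": "keep"},
                    {"evalue": 1e-3, "target_id": "drop"}],
                1: [{"evalue": 1e-6, "target_id": "other"}],
            }),
        ])
        pruned = [
            [h for h in full[0] if h.target_id != "drop"],
            full[1],
        ]
        a = pair_by_species(full)
        b = pair_by_species(pruned)
        assert [[r.identifier for r in blk.rows] for blk in a] == \
               [[r.identifier for r in blk.rows] for blk in b]

    def test_lower_coverage_threshold_never_loses_blocks(self):
        tables = make_species_hits(2, [
            layout_entry(1, {0: [{"coverage": 0.6}], 1: [{"coverage": 0.95}]}),
            layout_entry(2, {0: [{"coverage": 0.4}], 1: [{"coverage": 0.8}]}),
            layout_entry(3, {0: [{"coverage": 0.3}], 1: [{"coverage": 0.2}]}),
        ])
        counts = [len(pair_by_species(tables, min_query_cov=c))
                  for c in (0.9, 0.5, 0.35, 0.1)]
        assert counts == sorted(counts)
        assert counts[-1] == 3

    def test_missing_taxid_hit_ignored(self):
        tables = make_species_hits(2, [
            layout_entry(9606, {0: [{}], 1: [{}]}),
        ])
        tables[0][0].taxid = None
        assert pair_by_species(tables) == []


class TestAccessionOrdinal:
    def test_consecutive_accessions(self):
        assert accession_ordinal("A0A003") - accession_ordinal("A0A001") == 2

    def test_case_insensitive(self):
        assert accession_ordinal("a0a001") == accession_ordinal("A0A001")

    def test_unparseable(self):
        with pytest.raises(ValueError):
            accession_ordinal("__")


def genome_tables(chain0, chain1, taxid=1):
    return make_species_hits(2, [
        layout_entry(taxid, {
            0: [{"accession": a, "target_id": f"A{i}"} for i, a in enumerate(chain0)],
            1: [{"accession": a, "target_id": f"B{i}"} for i, a in enumerate(chain1)],
        }),
    ])


def brute_force_min_total_distance(chain0, chain1, max_gap):
    """Oracle: minimum total ordinal distance over all maximal matchings."""
    o0 = [accession_ordinal(a) for a in chain0]
    o1 = [accession_ordinal(a) for a in chain1]
    k = min(len(o0), len(o1))
    best = None
    for subset0 in itertools.permutations(range(len(o0)), k):
        for subset1 in itertools.permutations(range(len(o1)), k):
            dists = [abs(o0[i] - o1[j]) for i, j in zip(subset0, subset1)]
            if any(d > max_gap for d in dists):
                continue
            total = sum(dists)
            if best is None or total < best:
                best = total
    return best


class TestPairByGenomeDistance:
    def test_close_accessions_paired(self):
        blocks = pair_by_genome_distance(genome_tables(["A0A001"], ["A0A003"]),
                                         max_gap=10)
        assert len(blocks) == 1

    def test_distance_beyond_max_gap_rejected(self):
        blocks = pair_by_genome_distance(genome_tables(["A0A001"], ["A0A00Z"]),
                                         max_gap=10)
        assert blocks == []

    def test_greedy_matches_exhaustive_on_crafted_instance(self):
        # pairs: (001,003)=2 (001,004)=3 (005,003)=2 (005,004)=1
        chain0, chain1 = ["A0A001", "A0A005"], ["A0A003", "A0A004"]
        blocks = pair_by_genome_distance(genome_tables(chain0, chain1), max_gap=10)
        total = 0
        for b in blocks:
            accs = [r.accession for r in b.rows]
            total += abs(accession_ordinal(accs[0]) - accession_ordinal(accs[1]))
        assert len(blocks) == 2
        assert total == brute_force_min_total_distance(chain0, chain1, 10)

    def test_multiple_blocks_per_species(self):
        blocks = pair_by_genome_distance(
            genome_tables(["A0A001", "A0A100"], ["A0A002", "A0A101"]), max_gap=5
        )
        assert len(blocks) == 2

    def test_hit_without_accession_ignored(self):
        tables = genome_tables(["A0A001"], ["A0A002"])
        tables[1][0].accession = None
        assert pair_by_genome_distance(tables, max_gap=10) == []

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            pair_by_genome_distance([[]])
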