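"""Lowest-common-rank probabilities, thresholds and known/novel estimation."""

import numpy as np
import pytest

from taxbench import (LcrTable, RankOrder, ReferenceDB, ThidHistogram,
                      common_rank_prob, estimate_known_novel, lcr_table, mlr,
                      rank_identity_thresholds)
from taxbench.identity import identity_matrix
from taxbench._util import round_half_up
from taxbench.taxio import lcr

from conftest import ORDER, full_lineage, rec
from oracles import oracle_lcr_counts


class TestLcrTable:
    def test_worked_toy_counts(self):
        """Eight pairs at 90%: none conspecific, two congeneric, six confamilial."""
        table = LcrTable.from_counts({90: {"genus": 2, "family": 6}})
        assert table.p("species", 90) == 0.0
        assert table.p("genus", 90) == pytest.approx(2 / 8)
        assert table.p("family", 90) == pytest.approx(6 / 8)
        assert table.total_pairs(90) == 8

    def test_identical_full_lineages_all_species_at_100(self):
        db = ReferenceDB([rec(f"r{i}", "ACGTACGTACGTACGT", *full_lineage("G1", "S1"))
                          for i in range(4)])
        table = lcr_table(db)
        assert table.occupied() == [100]
        assert table.p("species", 100) == 1.0

    def test_against_enumeration_oracle(self, small_db, small_matrix):
        """Table counts equal a brute-force pairwise enumeration."""
        table = lcr_table(small_db, identities=small_matrix)
        n = len(small_db)
        triples = []
        for i in range(n):
            for j in range(i + 1, n):
                triples.append((round_half_up(small_matrix[i, j]),
                                small_db[i].taxonomy.names, small_db[j].taxonomy.names))
        expected = oracle_lcr_counts(triples, ORDER.ranks)
        assert table.counts == {d: row for d, row in expected.items()}

    def test_probabilities_sum_to_one_including_none(self, small_db, small_matrix):
        table = lcr_table(small_db, identities=small_matrix)
        ranks = list(ORDER.ranks) + [None]
        for d in table.occupied():
            total = sum(table.p(r, d) for r in ranks)
            assert total == pytest.approx(1.0)
            assert sum(table.counts[d].values()) == table.total_pairs(d)

    def test_missing_row_raises(self):
        table = LcrTable.from_counts({90: {"genus": 2}})
        with pytest.raises(KeyError):
            table.p("genus", 91)


class TestCommonRankProb:
    def test_cumulative_from_worked_counts(self):
        table = LcrTable.from_counts({90: {"genus": 2, "family": 6}})
        assert common_rank_prob(table, "species", 90) == 0.0
        assert common_rank_prob(table, "genus", 90) == pytest.approx(0.25)
        assert common_rank_prob(table, "family", 90) == pytest.approx(1.0)

    def test_lowest_rank_is_single_term(self):
        table = LcrTable.from_counts({97: {"species": 3, "genus": 5, "family": 2}})
        assert common_rank_prob(table, "species", 97) == table.p("species", 97)

    def test_none_mass_excluded_but_in_denominator(self):
        table = LcrTable.from_counts({80: {"family": 1, None: 3}})
        assert common_rank_prob(table, "family", 80) == pytest.approx(0.25)
        assert common_rank_prob(table, "domain", 80) == pytest.approx(0.25)

    def test_monotone_toward_higher_ranks(self, small_db, small_matrix):
        table = lcr_table(small_db, identities=small_matrix)
        for d in table.occupied():
            pcrs = [table.p_cr(r, d) for r in ORDER.ranks[::-1]]  # species -> domain
            assert all(b >= a - 1e-12 for a, b in zip(pcrs, pcrs[1:]))


class TestMlr:
    def test_highest_probability_wins(self):
        # probability profile .30/.49/.19/.03 across species..order: genus wins
        table = LcrTable.from_counts(
            {100: {"species": 30, "genus": 49, "family": 19, "order": 3}})
        assert mlr(table, 100) == "genus"

    def test_single_occupied_rank(self):
        table = LcrTable.from_counts({95: {"family": 7}})
        assert mlr(table, 95) == "family"

    def test_exact_tie_breaks_to_lower_rank(self):
        table = LcrTable.from_counts({95: {"genus": 5, "family": 5}})
        assert mlr(table, 95) == "genus"

    def test_none_never_wins(self):
        table = LcrTable.from_counts({60: {"phylum": 2, None: 98}})
        assert mlr(table, 60) == "phylum"


class TestRankIdentityThresholds:
    def test_worked_mlr_sequence(self):
        """MLR species at 100, genus over 94-99, family at 93 gives
        RIT(species)=100 and RIT(genus)=94."""
        counts = {100: {"species": 6, "genus": 4}}
        for d in range(94, 100):
            counts[d] = {"genus": 6, "species": 2, "family": 2}
        counts[93] = {"family": 7, "genus": 3}
        table = LcrTable.from_counts(counts)
        rit = rank_identity_thresholds(table)
        assert rit["species"] == 100
        assert rit["genus"] == 94
        assert rit["family"] == 93
        assert "order" not in rit  # never the most probable rank

    def test_constant_mlr_gives_min_occupied(self):
        table = LcrTable.from_counts({d: {"genus": 5} for d in (90, 94, 97)})
        rit = rank_identity_thresholds(table)
        assert rit == {"genus": 90}

    def test_matches_direct_scan(self, small_db, small_matrix):
        table = lcr_table(small_db, identities=small_matrix)
        rit = rank_identity_thresholds(table)
        for rank, threshold in rit.items():
            ds = [d for d in table.occupied() if table.mlr(d) == rank]
            assert threshold == min(ds)


class TestKnownNovelEstimate:
    def test_worked_example_70_known_30_novel(self):
        """100 OTUs all at 97% with species common-rank probability 0.7."""
        table = LcrTable.from_counts({97: {"species": 7, "genus": 3}})
        hist = ThidHistogram(counts={97: 100})
        est = estimate_known_novel(hist, table, "species")
        assert est.known == pytest.approx(70.0)
        assert est.novel == pytest.approx(30.0)

    def test_certain_table_gives_zero_novel(self):
        table = LcrTable.from_counts({d: {"species": 5} for d in (95, 100)})
        hist = ThidHistogram(counts={95: 12, 100: 8})
        est = estimate_known_novel(hist, table, "species")
        assert est.novel == pytest.approx(0.0)

    def test_two_bin_hand_computation(self):
        table = LcrTable.from_counts({100: {"species": 10},
                                      90: {"species": 2, "genus": 8}})
        hist = ThidHistogram(counts={100: 10, 90: 10})
        est = estimate_known_novel(hist, table, "species")
        assert est.known == pytest.approx(12.0)
        assert est.novel == pytest.approx(8.0)

    def test_conservation_per_bin_and_total(self):
        table = LcrTable.from_counts({95: {"species": 1, "genus": 3, "family": 4}})
        hist = ThidHistogram(counts={95: 37, 94: 13})  # 94 clamps to the 95 row
        est = estimate_known_novel(hist, table, "genus")
        for d, (k, v) in est.per_d.items():
            assert k + v == pytest.approx(hist.counts[d])
        assert est.known + est.novel == pytest.approx(50.0)

    def test_interpolation_between_rows(self):
        table = LcrTable.from_counts({90: {"genus": 5, "family": 5},
                                      100: {"species": 10}})
        hist = ThidHistogram(counts={95: 10})
        est = estimate_known_novel(hist, table, "genus")
        # P_CR(genus|90)=0.5, P_CR(genus|100)=1.0, midway -> 0.75
        assert est.per_d[95][0] == pytest.approx(7.5)


class TestParameterRecovery:
    def test_mlr_bands_recover_generating_ranks(self, small_db, small_matrix):
        """On a simulated reference the most probable LCR at the identity
        bands' centers is the rank that generated them, and the mean pair
        identity per true LCR decreases monotonically from species upward."""
        table = lcr_table(small_db, identities=small_matrix)
        n = len(small_db)
        per_rank: dict[str, list[float]] = {}
        for i in range(n):
            for j in range(i + 1, n):
                r = lcr(small_db[i].taxonomy, small_db[j].taxonomy, ORDER)
                per_rank.setdefault(r, []).append(small_matrix[i, j])
        means = [float(np.mean(per_rank[r])) for r in ORDER.ranks[::-1] if r in per_rank]
        assert all(a > b for a, b in zip(means, means[1:]))
        for rank in ("species", "genus"):
            center = round_half_up(float(np.median(per_rank[rank])))
            window = [d for d in table.occupied() if abs(d - center) <= 1]
            assert any(table.mlr(d) == rank for d in window), rank
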