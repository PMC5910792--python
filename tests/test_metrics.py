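"""Taxonomy-aware tallies, rates, averaging and benchmark orchestration."""

import numpy as np
import pytest

from taxbench import (Prediction, RankTally, ReferenceDB, average_over_identities,
                      evaluate_l1o, evaluate_run, default_specs, metrics_from_tally,
                      tally_rank)

from conftest import ORDER, full_lineage, rec


def pred(qid, genus=None):
    if genus is None:
        return Prediction(qid)
    names = dict(zip(ORDER.ranks, full_lineage(genus)))
    conf = {r: 1.0 for r in names}
    return Prediction(qid, names, conf)


@pytest.fixture()
def five_seq_case():
    """Three known-genus test sequences and two novel ones, with one of each
    outcome type: correct, misclassified, under-classified, over-classified."""
    truth = ReferenceDB([
        rec("t1", "ACGTACGT", *full_lineage("g1")),
        rec("t2", "ACGTACGT", *full_lineage("g2")),
        rec("t3", "ACGTACGT", *full_lineage("g3")),
        rec("x1", "ACGTACGT", *full_lineage("x1")),
        rec("x2", "ACGTACGT", *full_lineage("x2")),
    ])
    predictions = [pred("t1", "g1"), pred("t2", "g9"), pred("t3"),
                   pred("x1", "g1"), pred("x2")]
    training_names = {"g1", "g2", "g3", "g9"}
    return truth, predictions, training_names


class TestTallyRank:
    def test_hand_enumerated_counts(self, five_seq_case):
        truth, predictions, training_names = five_seq_case
        t = tally_rank(truth, predictions, training_names, "genus")
        assert (t.N, t.K, t.L) == (5, 3, 2)
        assert (t.TP, t.MC, t.UC, t.OC) == (1, 1, 1, 1)
        assert t.TP + t.MC + t.UC == t.K  # conservation

    def test_all_correct_no_novel(self):
        truth = ReferenceDB([rec(f"t{i}", "ACGT", *full_lineage(f"g{i}"))
                             for i in range(4)])
        predictions = [pred(f"t{i}", f"g{i}") for i in range(4)]
        t = tally_rank(truth, predictions, {f"g{i}" for i in range(4)}, "genus")
        assert (t.TP, t.K, t.N) == (4, 4, 4)
        assert (t.MC, t.OC, t.UC) == (0, 0, 0)

    def test_truncated_truth_excluded_from_n(self):
        truth = ReferenceDB([
            rec("a", "ACGT", *full_lineage("g1", "s1")),
            rec("b", "ACGT", *full_lineage("g2")),  # no species annotation
        ])
        predictions = [pred("a", "g1"), pred("b", "g2")]
        t = tally_rank(truth, predictions, {"s1"}, "species")
        assert t.N == 1

    def test_foreign_prediction_id_rejected(self, five_seq_case):
        truth, predictions, training_names = five_seq_case
        predictions.append(pred("ghost", "g1"))
        with pytest.raises(ValueError, match="ghost"):
            tally_rank(truth, predictions, training_names, "genus")


class TestMetricsFromTally:
    def test_hand_arithmetic_with_rule_disabled(self, five_seq_case):
        truth, predictions, training_names = five_seq_case
        t = tally_rank(truth, predictions, training_names, "genus")
        row = metrics_from_tally(t, min_denominator=1)
        assert row["TPR"] == pytest.approx(100 / 3)
        assert row["UCR"] == pytest.approx(100 / 3)
        assert row["MCR"] == pytest.approx(100 / 3)
        assert row["OCR"] == pytest.approx(50.0)
        assert row["Acc"] == pytest.approx(25.0)     # TP / (K + OC) = 1/4
        assert row["AccRDP"] == pytest.approx(20.0)  # TP / N = 1/5

    def test_rule_of_ten_suppresses_small_denominators(self, five_seq_case):
        truth, predictions, training_names = five_seq_case
        t = tally_rank(truth, predictions, training_names, "genus")
        row = metrics_from_tally(t)  # denominators 3, 2, 4 and 5 are all < 10
        assert all(row[m] is None for m in ("TPR", "UCR", "MCR", "OCR", "Acc", "AccRDP"))

    def test_zero_novel_count_suppresses_ocr(self):
        t = RankTally("genus", N=50, K=50, TP=50)
        row = metrics_from_tally(t)
        assert row["OCR"] is None
        assert row["TPR"] == pytest.approx(100.0)

    def test_full_predictions_make_acc_equal_accrdp(self):
        # UC = 0 and OC = L: Acc = TP/(K+L) = TP/N
        t = RankTally("genus", N=40, K=30, TP=25, MC=5, OC=10, UC=0)
        row = metrics_from_tally(t)
        assert row["Acc"] == pytest.approx(row["AccRDP"])

    def test_accrdp_bounded_by_known_fraction(self):
        t = RankTally("genus", N=40, K=30, TP=30, MC=0, OC=10, UC=0)
        row = metrics_from_tally(t)
        assert row["AccRDP"] <= 100.0 * t.K / t.N + 1e-9


class TestAveraging:
    def test_identical_rows_average_to_same_value(self):
        rows = {d: {"TPR": 80.0, "UCR": 5.0, "MCR": 15.0, "OCR": 50.0,
                    "Acc": 60.0, "AccRDP": 55.0} for d in (100, 99, 97)}
        avg = average_over_identities(rows)
        assert avg["TPR"] == (pytest.approx(80.0), 3)

    def test_simple_two_row_mean(self):
        rows = {100: {"Acc": 100.0}, 99: {"Acc": 50.0}}
        avg = average_over_identities(rows)
        assert avg["Acc"] == (pytest.approx(75.0), 2)

    def test_unreported_rows_skipped_with_count(self):
        rows = {100: {"OCR": None}}
        rows.update({d: {"OCR": 100.0} for d in (99, 97, 95, 90)})
        avg = average_over_identities(rows)
        assert avg["OCR"] == (pytest.approx(100.0), 4)

    def test_all_unreported_gives_none(self):
        avg = average_over_identities({100: {"OCR": None}})
        assert avg["OCR"] == (None, 0)


class TestEvaluateRun:
    def test_top_hit_structural_rates_under_cvi(self, small_db, small_matrix):
        """The top-hit classifier always predicts a full lineage, so under
        identity-constrained cross-validation its under-classification rate
        is 0 and its over-classification rate 100 at every reportable
        identity."""
        report = evaluate_run(small_db, default_specs(3), "top", seed=3,
                              identities=small_matrix, min_denominator=1)
        assert report.avg_value("genus", "UCR") == pytest.approx(0.0)
        genus = report.rows[report.rows["rank"] == "genus"]
        assert genus["L"].sum() > 0
        assert report.avg_value("genus", "OCR") == pytest.approx(100.0)
        assert (genus["TP"] + genus["MC"] + genus["UC"]).equals(genus["K"])
        assert (genus["UC"] == 0).all()
        assert (genus["OC"] == genus["L"]).all()

    def test_identity_100_with_unique_lineages_is_perfect(self):
        records = []
        base = np.random.default_rng(0).choice(list("ACGT"), 60)
        for i in range(12):
            seq = base.copy()
            seq[5 * i: 5 * i + 3] = list("TTT") if seq[5 * i] != "T" else list("AAA")
            records.append(rec(f"u{i}", "".join(seq),
                               *full_lineage(f"g{i}", f"s{i}")))
        db = ReferenceDB(records)
        report = evaluate_run(db, [s for s in default_specs(0) if s.d == 100.0],
                              "top", min_denominator=1)
        for rank in ORDER.ranks:
            assert report.row(rank, 100.0)["TPR"] == pytest.approx(100.0)

    def test_accuracy_declines_from_d100_to_d90(self, small_db, small_matrix):
        report = evaluate_run(small_db, default_specs(1), "top", seed=1,
                              identities=small_matrix, min_denominator=1)
        acc100 = report.row("genus", 100.0)["Acc"]
        acc90 = report.row("genus", 90.0)["Acc"]
        assert acc100 >= acc90

    def test_cutoff_monotonicity_of_oc_and_uc(self, small_db, small_matrix):
        """Raising the bootstrap cutoff never adds over-classifications and
        never removes under-classifications."""
        specs = [s for s in default_specs(2) if s.d in (97.0, 90.0)]
        prev_oc, prev_uc = None, None
        for cutoff in (0.0, 0.5, 0.8):
            report = evaluate_run(small_db, specs, "sintax", cutoff=cutoff,
                                  seed=2, identities=small_matrix, min_denominator=1)
            genus = report.rows[report.rows["rank"] == "genus"]
            oc, uc = int(genus["OC"].sum()), int(genus["UC"].sum())
            if prev_oc is not None:
                assert oc <= prev_oc
                assert uc >= prev_uc
            prev_oc, prev_uc = oc, uc

    def test_deterministic_given_seed(self, small_db, small_matrix):
        specs = [s for s in default_specs(4) if s.d in (97.0,)]
        a = evaluate_run(small_db, specs, "nbc", cutoff=0.5, seed=4,
                         identities=small_matrix, min_denominator=1)
        b = evaluate_run(small_db, specs, "nbc", cutoff=0.5, seed=4,
                         identities=small_matrix, min_denominator=1)
        assert a.rows.equals(b.rows)


class TestEvaluateL1O:
    def test_full_prediction_methods_have_acc_equal_accrdp(self, small_db, small_matrix):
        """With a cutoff of zero every query receives a full prediction, so
        UC = 0, OC = L and the two accuracy definitions coincide."""
        report = evaluate_l1o(small_db, "sintax", cutoff=0.0, seed=1,
                              identities=small_matrix, min_denominator=1)
        for rank in ("genus", "family"):
            row = report.rows[report.rows["rank"] == rank].iloc[0]
            assert row["UC"] == 0
            assert row["OC"] == row["L"]
            assert row["Acc"] == pytest.approx(row["AccRDP"])

    def test_singleton_taxa_are_novel(self):
        db = ReferenceDB([
            rec("a", "ACGTACGTACGTACGTACGT", *full_lineage("g1", "s1")),
            rec("b", "ACGTACGTACGTACGTACGA", *full_lineage("g1", "s2")),
            rec("c", "ACGTACGTACGTACGTTTTT", *full_lineage("g2", "s3")),
        ])
        report = evaluate_l1o(db, "top", min_denominator=1)
        genus = report.rows[report.rows["rank"] == "genus"].iloc[0]
        assert genus["K"] == 2 and genus["L"] == 1  # g2 is a singleton
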