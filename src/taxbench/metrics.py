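"""Taxonomy-aware accuracy metrics and benchmark orchestration.

For a test set of N sequences evaluated at one rank, K is the number whose
true name at that rank is present in the training set (known) and L = N - K
the number whose name is absent (novel).  Each prediction contributes one
event:

* known, predicted correctly           -> TP
* known, predicted with another name   -> MC (misclassification)
* known, no prediction at the rank     -> UC (under-classification)
* novel, any prediction at the rank    -> OC (over-classification)
* novel, no prediction                 -> no event (not a true negative:
  correctness cannot be determined)

Rates divide each error count by its opportunity count: TPR = TP/K,
UCR = UC/K, MCR = MC/K, OCR = OC/L.  Accuracy is Acc = TP/(K + OC) — correct
predictions over predictions whose correctness can be determined — and the
leave-one-out literature's Acc_RDP = TP/N (bounded above by K/N).  A rate is
unreported when its denominator is below a minimum count (default 10).
Per-rank metrics computed at several top-hit identities d are summarized by
their unweighted mean over the identities where the metric is reported
(Avg prefix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._util import derive_seed, round_half_up
from .classify import (Prediction, SintaxIndex, nbc_classify, sintax_classify,
                       top_classify, train_nbc)
from .cvisplit import SplitResult, SplitSpec, build_split, default_specs, verify_split
from .identity import identity_matrix
from .taxio import ReferenceDB

logger = logging.getLogger(__name__)

MIN_DENOMINATOR = 10  # minimum test cases required to report a rate

RATE_COLUMNS = ("TPR", "UCR", "MCR", "OCR", "Acc", "AccRDP")


@dataclass
class RankTally:
    """Event counts for one rank of one test/training pair."""

    rank: str
    N: int = 0
    K: int = 0
    TP: int = 0
    MC: int = 0
    OC: int = 0
    UC: int = 0

    @property
    def L(self) -> int:
        return self.N - self.K


def tally_rank(truth: ReferenceDB, predictions, training_names: set[str],
               rank: str) -> RankTally:
    """Tally TP/MC/OC/UC for one rank.

    ``truth`` is the test set with its authoritative annotations;
    ``training_names`` are the names present in the training set at ``rank``.
    Test sequences without a name at ``rank`` are excluded from N.
    """
    pred_map = _prediction_map(predictions)
    unknown = set(pred_map) - set(truth.ids)
    if unknown:
        raise ValueError(f"predictions for ids absent from the test set: {sorted(unknown)[:5]}")
    t = RankTally(rank)
    for rec in truth:
        true_name = rec.taxonomy.name_at(rank, truth.rank_order)
        if true_name is None:
            continue
        t.N += 1
        pred = pred_map.get(rec.id)
        pred_name = pred.name_at(rank) if pred is not None else None
        if true_name in training_names:
            t.K += 1
            if pred_name is None:
                t.UC += 1
            elif pred_name == true_name:
                t.TP += 1
            else:
                t.MC += 1
        elif pred_name is not None:
            t.OC += 1
    return t


def _prediction_map(predictions) -> dict[str, Prediction]:
    if isinstance(predictions, dict):
        return predictions
    return {p.query_id: p for p in predictions}


def metrics_from_tally(t: RankTally, min_denominator: int = MIN_DENOMINATOR) -> dict:
    """Percent rates from a tally; ``None`` marks an unreported metric."""

    def rate(num: int, denom: int) -> Optional[float]:
        if denom < max(min_denominator, 1):
            return None
        return 100.0 * num / denom

    return {
        "rank": t.rank, "N": t.N, "K": t.K, "L": t.L,
        "TP": t.TP, "MC": t.MC, "OC": t.OC, "UC": t.UC,
        "TPR": rate(t.TP, t.K), "UCR": rate(t.UC, t.K), "MCR": rate(t.MC, t.K),
        "OCR": rate(t.OC, t.L),
        "Acc": rate(t.TP, t.K + t.OC), "AccRDP": rate(t.TP, t.N),
    }


def average_over_identities(rows: dict[float, dict]) -> dict:
    """Unweighted mean of each metric over the identities where it is reported.

    Returns ``{metric: (mean or None, contributing count)}``.
    """
    out = {}
    for metric in RATE_COLUMNS:
        vals = [row[metric] for row in rows.values() if row.get(metric) is not None]
        out[metric] = (float(np.mean(vals)) if vals else None, len(vals))
    return out


@dataclass
class MetricsReport:
    """Per-(rank, identity) metric rows plus per-rank Avg summaries."""

    rows: pd.DataFrame   # columns: rank, d, N, K, L, TP, MC, OC, UC, rates
    avg: pd.DataFrame    # columns: rank, metric, value, n_d

    def avg_value(self, rank: str, metric: str) -> Optional[float]:
        sel = self.avg[(self.avg["rank"] == rank) & (self.avg["metric"] == metric)]
        if sel.empty:
            return None
        v = sel["value"].iloc[0]
        return None if pd.isna(v) else float(v)

    def row(self, rank: str, d: float) -> dict:
        sel = self.rows[(self.rows["rank"] == rank) & (self.rows["d"] == d)]
        return sel.iloc[0].to_dict()

    def to_tsv(self, path) -> None:
        with open(path, "w") as out:
            cols = ["rank", "d", "N", "K", "L", "TP", "MC", "OC", "UC", *RATE_COLUMNS]
            out.write("\t".join(cols) + "\n")
            for _, r in self.rows.iterrows():
                vals = [str(r["rank"]), f"{r['d']:g}"]
                vals += [str(int(r[c])) for c in ("N", "K", "L", "TP", "MC", "OC", "UC")]
                vals += ["NA" if pd.isna(r[c]) else f"{r[c]:.1f}" for c in RATE_COLUMNS]
                out.write("\t".join(vals) + "\n")
            for _, r in self.avg.iterrows():
                val = "NA" if pd.isna(r["value"]) else f"{r['value']:.1f}"
                out.write(f"{r['rank']}\tAvg{r['metric']}\t{val}\t(n_d={int(r['n_d'])})\n")


def _classify_test_set(test: ReferenceDB, training: ReferenceDB, method: str, *,
                       cutoff: float, seed: int, n_boot: int,
                       exclude_self: bool = False,
                       top_identities: Optional[np.ndarray] = None,
                       test_positions: Optional[Sequence[int]] = None,
                       training_positions: Optional[Sequence[int]] = None) -> list[Prediction]:
    """Run one classifier over a test set against a training set.

    For the global-alignment top-hit method a precomputed identity matrix
    over the parent reference can be supplied (with each set's row/column
    positions) to avoid realignment.
    """
    preds: list[Prediction] = []
    if method == "top" and top_identities is not None:
        t_pos = np.asarray(training_positions)
        train_ids = training.ids
        for rec, q_pos in zip(test, test_positions):
            cols = t_pos
            if exclude_self and rec.id in training:
                cols = t_pos[t_pos != q_pos]
            if cols.size == 0:
                preds.append(Prediction(rec.id))
                continue
            best = int(np.argmax(top_identities[q_pos, cols]))
            lineage = training.get(train_ids[int(np.searchsorted(t_pos, cols[best]))]).taxonomy
            order = training.rank_order
            preds.append(Prediction(rec.id,
                                    dict(zip(order.ranks, lineage.names)),
                                    {order.ranks[i]: 1.0 for i in range(lineage.depth)}))
        return preds
    if method in ("top", "ktop", "ltop"):
        mode = {"top": "global", "ktop": "kmer", "ltop": "local"}[method]
        return [top_classify(q, training, mode=mode, exclude_self=exclude_self) for q in test]
    if method == "nbc":
        model = train_nbc(training)
        return [nbc_classify(q, model, cutoff=cutoff, n_boot=n_boot, seed=seed,
                             exclude_self=exclude_self) for q in test]
    if method == "sintax":
        index = SintaxIndex(training)
        return [sintax_classify(q, training, cutoff=cutoff, n_boot=n_boot, seed=seed,
                                exclude_self=exclude_self, index=index) for q in test]
    raise ValueError(f"unknown method {method!r}")


def evaluate_run(db: ReferenceDB,
                 specs: Union[Iterable[SplitSpec], Iterable[SplitResult], None] = None,
                 method: str = "top", *, cutoff: float = 0.0, seed: int = 0,
                 n_boot: int = 100, identities: Optional[np.ndarray] = None,
                 min_denominator: int = MIN_DENOMINATOR,
                 ranks: Optional[Sequence[str]] = None,
                 verify: bool = True) -> MetricsReport:
    """Full identity-constrained cross-validation benchmark of one method.

    Builds (or accepts) a split per target identity, classifies every test
    sequence against its training set, tallies every rank at every identity
    and assembles the averaged report.  Identities whose test set is empty
    contribute no rows.  Deterministic given the seed.
    """
    if specs is None:
        specs = default_specs(seed)
    specs = list(specs)
    ranks = list(ranks if ranks is not None else db.rank_order.ranks)
    if identities is None:
        identities = identity_matrix(db)

    rows: list[dict] = []
    per_rank_rows: dict[str, dict[float, dict]] = {r: {} for r in ranks}
    for item in specs:
        if isinstance(item, SplitResult):
            split = item
        else:
            split = build_split(db, item, identities=identities)
        d = split.spec.d
        if verify:
            report = verify_split(db, split, identities=identities)
            if not report.ok:
                raise RuntimeError(f"split at d={d} failed verification: "
                                   f"{report.violations[:3]}")
        if not split.S:
            logger.warning("empty test set at d=%g; no metrics for this identity", d)
            continue
        test = db.subset(split.S)
        training = db.subset(split.training)
        test_pos = [db.position(i) for i in test.ids]
        train_pos = [db.position(i) for i in training.ids]
        preds = _classify_test_set(
            test, training, method, cutoff=cutoff,
            seed=derive_seed(seed, "classify", d), n_boot=n_boot,
            exclude_self=False, top_identities=identities,
            test_positions=test_pos, training_positions=train_pos)
        for rank in ranks:
            tally = tally_rank(test, preds, training.names_at(rank), rank)
            row = metrics_from_tally(tally, min_denominator)
            row["d"] = d
            rows.append(row)
            per_rank_rows[rank][d] = row

    avg_rows = []
    for rank in ranks:
        averages = average_over_identities(per_rank_rows[rank])
        for metric, (value, n_d) in averages.items():
            avg_rows.append({"rank": rank, "metric": metric,
                             "value": np.nan if value is None else value, "n_d": n_d})
    return MetricsReport(pd.DataFrame(rows), pd.DataFrame(avg_rows))


def evaluate_l1o(db: ReferenceDB, method: str = "top", *, cutoff: float = 0.0,
                 seed: int = 0, n_boot: int = 100,
                 identities: Optional[np.ndarray] = None,
                 min_denominator: int = MIN_DENOMINATOR,
                 ranks: Optional[Sequence[str]] = None) -> MetricsReport:
    """Leave-one-out benchmark: each sequence classified against the rest.

    The training set for each query is the reference minus that query,
    realized by id-masking.  Known names at a rank are those carried by at
    least one *other* sequence, so singleton taxa are novel.
    """
    if len(db) < 2:
        raise ValueError("need at least two records for leave-one-out")
    ranks = list(ranks if ranks is not None else db.rank_order.ranks)
    n = len(db)
    if method == "top":
        if identities is None:
            identities = identity_matrix(db)
        preds = _classify_test_set(db, db, "top", cutoff=cutoff, seed=seed,
                                   n_boot=n_boot, exclude_self=True,
                                   top_identities=identities,
                                   test_positions=range(n),
                                   training_positions=range(n))
    else:
        preds = _classify_test_set(db, db, method, cutoff=cutoff,
                                   seed=derive_seed(seed, "l1o"), n_boot=n_boot,
                                   exclude_self=True)

    # per-rank name multiplicities decide novelty under masking
    rows = []
    per_rank: dict[str, dict[float, dict]] = {}
    for rank in ranks:
        name_counts: dict[str, int] = {}
        for rec in db:
            name = rec.taxonomy.name_at(rank, db.rank_order)
            if name is not None:
                name_counts[name] = name_counts.get(name, 0) + 1
        t = RankTally(rank)
        pred_map = _prediction_map(preds)
        for rec in db:
            true_name = rec.taxonomy.name_at(rank, db.rank_order)
            if true_name is None:
                continue
            t.N += 1
            pred = pred_map.get(rec.id)
            pred_name = pred.name_at(rank) if pred is not None else None
            if name_counts[true_name] > 1:  # known once this record is masked
                t.K += 1
                if pred_name is None:
                    t.UC += 1
                elif pred_name == true_name:
                    t.TP += 1
                else:
                    t.MC += 1
            elif pred_name is not None:
                t.OC += 1
        row = metrics_from_tally(t, min_denominator)
        row["d"] = np.nan
        rows.append(row)
        per_rank[rank] = {0.0: row}

    avg_rows = []
    for rank in ranks:
        for metric, (value, n_d) in average_over_identities(per_rank[rank]).items():
            avg_rows.append({"rank": rank, "metric": metric,
                             "value": np.nan if value is None else value, "n_d": n_d})
    return MetricsReport(pd.DataFrame(rows), pd.DataFrame(avg_rows))
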