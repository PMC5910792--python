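"""Baseline taxonomy classifiers.

Four prediction strategies are provided, mirroring the common families of
marker-gene classifiers:

* ``top_classify`` — copy the full lineage of the best database hit, using
  global alignment identity, local alignment identity, or shared unique
  eight-mer counts (the k-mer variant is a zero-bootstrap analogue of
  word-voting classifiers).
* ``train_nbc``/``nbc_classify`` — naive Bayes over unique eight-mers with
  per-genus document frequencies and bootstrap confidence (RDP-style).
* ``sintax_classify`` — bootstrap word voting over database records: each
  bootstrap draws words from the query, votes the lineage of the record
  sharing the most drawn words, and per-rank confidence is the vote
  agreement with the full-word winner.

Predictions are gapless rank prefixes truncated at the first rank whose
confidence falls below the cutoff; a confidence exactly at the cutoff is
kept.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._util import derive_seed
from .identity import top_hit, unique_kmers
from .taxio import RankOrder, ReferenceDB, TaxSeqRecord, Taxonomy

logger = logging.getLogger(__name__)

WORD_SIZE = 8


@dataclass
class Prediction:
    """A per-query predicted lineage with per-rank confidences.

    ``names`` covers a gapless leading run of the rank order; every named
    rank has confidence >= ``cutoff``.
    """

    query_id: str
    names: dict[str, str] = field(default_factory=dict)
    confidence: dict[str, float] = field(default_factory=dict)
    cutoff: float = 0.0

    @property
    def empty(self) -> bool:
        return not self.names

    def name_at(self, rank: str) -> Optional[str]:
        return self.names.get(rank)

    def format_lineage(self, order: RankOrder) -> str:
        full = ",".join(
            f"{order.letter(r)}:{self.names[r]}({self.confidence.get(r, 1.0):.2f})"
            for r in order if r in self.names)
        return full or "*"


def _truncate(query_id: str, lineage: Taxonomy, conf: list[float],
              cutoff: float, order: RankOrder) -> Prediction:
    """Keep the leading ranks whose confidence clears the cutoff."""
    names: dict[str, str] = {}
    confidence: dict[str, float] = {}
    for i, name in enumerate(lineage.names):
        if conf[i] < cutoff:
            break
        names[order.ranks[i]] = name
        confidence[order.ranks[i]] = conf[i]
    return Prediction(query_id, names, confidence, cutoff)


def top_classify(query: TaxSeqRecord, db: ReferenceDB, mode: str = "global",
                 exclude_self: bool = False) -> Prediction:
    """Predict the query taxonomy as the full lineage of its top hit.

    Confidence is 1.0 at every rank, so novel taxa are always
    over-classified when any hit is found; ties go to the earliest record.
    ``mode`` is ``global``, ``local`` or ``kmer``.
    """
    metric = "kmer" if mode == "kmer" else "alignment"
    aln_mode = "global" if mode == "kmer" else mode
    hit = top_hit(query, db, metric=metric, exclude_self=exclude_self, mode=aln_mode)
    if hit is None:
        return Prediction(query.id)
    lineage = db.get(hit.target_id).taxonomy
    conf = [1.0] * lineage.depth
    return _truncate(query.id, lineage, conf, 0.0, db.rank_order)


# ---------------------------------------------------------------------------
# Naive Bayes (bootstrap) classifier

@dataclass
class NbcModel:
    """Per-genus word statistics for the naive Bayes classifier.

    ``word_index`` maps each training word to a row of ``doc_freq``, whose
    columns follow ``genus_names`` (training input order).  ``doc_freq[w,g]``
    counts the genus-g sequences containing word w; the smoothed conditional
    word probability is (count + 0.5) / (N_g + 1).
    """

    k: int
    rank_order: RankOrder
    genus_names: list[str]
    genus_lineages: dict[str, Taxonomy]
    genus_counts: np.ndarray          # sequences per genus
    word_index: dict[str, int]
    doc_freq: np.ndarray              # (n_words, n_genera)

    def log_probs(self, words: list[str],
                  exclude: Optional[tuple[int, frozenset[str]]] = None) -> np.ndarray:
        """(len(words), n_genera) matrix of log P(w | g).

        ``exclude=(genus index, word set)`` removes one training sequence's
        contribution at query time (leave-one-out masking without retraining).
        """
        counts = self.genus_counts.copy()
        if exclude is not None:
            counts[exclude[0]] -= 1
        denom = counts + 1.0
        missing = np.log(0.5 / denom)
        out = np.empty((len(words), len(self.genus_names)))
        for i, w in enumerate(words):
            row = self.word_index.get(w)
            if row is None:
                out[i] = missing
                continue
            df = self.doc_freq[row].astype(float)
            if exclude is not None and w in exclude[1]:
                df[exclude[0]] -= 1
            out[i] = np.log((df + 0.5) / denom)
        if exclude is not None and counts[exclude[0]] <= 0:
            out[:, exclude[0]] = -np.inf  # genus emptied by masking: not a candidate
        return out


def train_nbc(db: ReferenceDB) -> NbcModel:
    """Train the naive Bayes model; every record must be annotated to genus.

    The model predicts lineages down to genus (its class variable); each
    genus keeps the lineage of its first record.
    """
    order = db.rank_order
    genus_rank = "genus" if "genus" in order else order.ranks[-1]
    genus_names: list[str] = []
    genus_pos: dict[str, int] = {}
    lineages: dict[str, Taxonomy] = {}
    seq_words: list[tuple[int, frozenset[str]]] = []
    for rec in db:
        g = rec.taxonomy.name_at(genus_rank, order)
        if g is None:
            raise ValueError(f"record {rec.id!r} lacks a {genus_rank} annotation")
        if g not in genus_pos:
            genus_pos[g] = len(genus_names)
            genus_names.append(g)
            lineages[g] = rec.taxonomy.truncate(genus_rank, order)
        elif lineages[g].names != rec.taxonomy.truncate(genus_rank, order).names:
            logger.warning("genus %r has conflicting lineages; keeping the first", g)
        seq_words.append((genus_pos[g], unique_kmers(rec.sequence, WORD_SIZE)))

    vocab = sorted(set().union(*(w for _, w in seq_words)) if seq_words else set())
    word_index = {w: i for i, w in enumerate(vocab)}
    doc_freq = np.zeros((len(vocab), len(genus_names)), dtype=np.int32)
    counts = np.zeros(len(genus_names))
    for g_idx, words in seq_words:
        counts[g_idx] += 1
        for w in words:
            doc_freq[word_index[w], g_idx] += 1
    return NbcModel(WORD_SIZE, order, genus_names, lineages, counts, word_index, doc_freq)


def nbc_classify(query: TaxSeqRecord, model: NbcModel, cutoff: float = 0.8,
                 n_boot: int = 100, seed: int = 0,
                 exclude_self: bool = False) -> Prediction:
    """Naive Bayes prediction with bootstrap confidence.

    The predicted lineage is that of the genus maximizing the full-word log
    score sum(log P(w|g)) over the query's unique words.  Each of ``n_boot``
    bootstraps draws floor(V/8) words with replacement from the V unique
    query words; confidence at a rank is the fraction of bootstrap winners
    agreeing with the predicted name there.  Bit-reproducible given
    (seed, query id, n_boot).
    """
    word_set = unique_kmers(query.sequence, model.k)
    words = sorted(word_set)
    if not words:
        return Prediction(query.id, cutoff=cutoff)
    exclude = None
    if exclude_self:
        genus_rank = "genus" if "genus" in model.rank_order else model.rank_order.ranks[-1]
        g = query.taxonomy.name_at(genus_rank, model.rank_order)
        if g in model.genus_names:
            exclude = (model.genus_names.index(g), word_set)
    logp = model.log_probs(words, exclude=exclude)   # (V, G)
    full_winner = int(np.argmax(logp.sum(axis=0)))
    lineage = model.genus_lineages[model.genus_names[full_winner]]

    rng = np.random.default_rng(derive_seed(seed, "nbc", query.id))
    n_draw = max(1, len(words) // 8)
    idx = rng.integers(0, len(words), size=(n_boot, n_draw))
    winners = np.argmax(logp[idx].sum(axis=1), axis=1)   # (n_boot,)

    conf = _agreement_confidence(
        lineage, [model.genus_lineages[model.genus_names[w]] for w in winners], n_boot)
    return _truncate(query.id, lineage, conf, cutoff, model.rank_order)


def _agreement_confidence(lineage: Taxonomy, voted: list[Taxonomy], n_boot: int) -> list[float]:
    """Per-rank fraction of votes agreeing with ``lineage``."""
    conf = []
    for i, name in enumerate(lineage.names):
        agree = sum(1 for v in voted if i < v.depth and v.names[i] == name)
        conf.append(agree / n_boot)
    return conf


# ---------------------------------------------------------------------------
# k-mer bootstrap (word-voting) classifier

class SintaxIndex:
    """Posting lists (word -> record indices) over a reference database."""

    def __init__(self, db: ReferenceDB, k: int = WORD_SIZE):
        self.db = db
        self.k = k
        self.postings: dict[str, np.ndarray] = {}
        lists: dict[str, list[int]] = {}
        for i, rec in enumerate(db):
            for w in unique_kmers(rec.sequence, k):
                lists.setdefault(w, []).append(i)
        self.postings = {w: np.asarray(v, dtype=np.int64) for w, v in lists.items()}

    def shared_counts(self, words: dict[str, int]) -> np.ndarray:
        """Per-record counts of drawn words (with multiplicity)."""
        counts = np.zeros(len(self.db))
        for w, mult in words.items():
            hit = self.postings.get(w)
            if hit is not None:
                counts[hit] += mult
        return counts


def sintax_classify(query: TaxSeqRecord, db: ReferenceDB, cutoff: float = 0.8,
                    n_boot: int = 100, words_per_boot: int = 32, seed: int = 0,
                    exclude_self: bool = False,
                    index: Optional[SintaxIndex] = None) -> Prediction:
    """Bootstrap word-voting prediction.

    The predicted lineage is that of the record sharing most of the query's
    full unique-word set (ties to the earliest record); each bootstrap draws
    ``words_per_boot`` words with replacement and votes the lineage of the
    record sharing most drawn words.  Bootstraps sharing no word vote for
    nothing.  With cutoff 0 the prediction equals the k-mer top hit.
    """
    if index is None:
        index = SintaxIndex(db)
    words = sorted(unique_kmers(query.sequence, index.k))
    if not words:
        return Prediction(query.id, cutoff=cutoff)
    excluded = db.position(query.id) if exclude_self and query.id in db else None

    def winner(counts: np.ndarray) -> Optional[int]:
        if excluded is not None:
            counts = counts.copy()
            counts[excluded] = -1.0
        best = int(np.argmax(counts))
        return best if counts[best] > 0 else None

    full = winner(index.shared_counts({w: 1 for w in words}))
    if full is None:
        return Prediction(query.id, cutoff=cutoff)
    lineage = db[full].taxonomy

    rng = np.random.default_rng(derive_seed(seed, "sintax", query.id))
    voted: list[Taxonomy] = []
    for _ in range(n_boot):
        draw = rng.integers(0, len(words), size=words_per_boot)
        tally = Counter(words[i] for i in draw)
        w = winner(index.shared_counts(dict(tally)))
        if w is not None:
            voted.append(db[w].taxonomy)
    conf = _agreement_confidence(lineage, voted, n_boot)
    return _truncate(query.id, lineage, conf, cutoff, db.rank_order)
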