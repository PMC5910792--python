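"""Pairwise sequence identity, k-mer similarity and top-hit searches.

Identity is the fraction of matching columns in a pairwise alignment:

* ``global`` mode: global alignment with lightly penalized terminal gaps;
  terminal gap columns are excluded from the identity column count.
* ``local`` mode: best local alignment; identity over its columns.

Scoring is match +1, mismatch -2; an internal affine gap of length L costs
10 + (L - 1) and a terminal gap costs 1 per position.  The light (but
nonzero) terminal-gap penalty matters: with fully free end gaps and a
mismatch penalty of this size, the optimal alignment of two sequences below
~67% identity degenerates into a short perfect staggered overlap that
reports as 100% identity.  Penalizing end gaps keeps homologous markers
aligned over their full overlap while still tolerating length differences.
Integer identities round half up.
"""

from __future__ import annotations

import threading
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio import Align

from ._util import round_half_up
from .taxio import ReferenceDB, TaxSeqRecord

MATCH_SCORE = 1.0
MISMATCH_SCORE = -2.0
GAP_OPEN_SCORE = -10.0
GAP_EXTEND_SCORE = -1.0
END_GAP_SCORE = -1.0  # per terminal gap position

_local = threading.local()


def _aligner(mode: str) -> Align.PairwiseAligner:
    cache = getattr(_local, "aligners", None)
    if cache is None:
        cache = _local.aligners = {}
    if mode not in cache:
        if mode not in ("global", "local"):
            raise ValueError(f"unknown alignment mode {mode!r}")
        a = Align.PairwiseAligner()
        a.mode = mode
        a.match_score = MATCH_SCORE
        a.mismatch_score = MISMATCH_SCORE
        a.open_gap_score = GAP_OPEN_SCORE
        a.extend_gap_score = GAP_EXTEND_SCORE
        if mode == "global":
            a.open_end_gap_score = END_GAP_SCORE
            a.extend_end_gap_score = END_GAP_SCORE
        cache[mode] = a
    return cache[mode]


@dataclass(frozen=True)
class PairIdentity:
    """Percent identity of one sequence pair."""

    id_a: str
    id_b: str
    identity_raw: float
    identity_int: int


@dataclass(frozen=True)
class TopHit:
    """Best database match for a query.

    ``score`` is the quantity that was maximized: alignment identity in
    alignment metrics, shared unique-word count in the k-mer metric.
    """

    query_id: str
    target_id: str
    identity_raw: float
    identity_int: int
    score: float


@dataclass
class ThidHistogram:
    """Top-hit identity distribution: query count per integer identity.

    ``annotations`` optionally carries the most probable lowest common rank
    for each occupied identity.
    """

    counts: dict[int, int] = field(default_factory=dict)
    annotations: Optional[dict[int, Optional[str]]] = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_tsv(self, path) -> None:
        with open(path, "w") as out:
            out.write("d\tN_d\tMLR\n")
            for d in sorted(self.counts, reverse=True):
                mlr = (self.annotations or {}).get(d) or "NA"
                out.write(f"{d}\t{self.counts[d]}\t{mlr}\n")


def _identity_from_rows(row_a: str, row_b: str) -> float:
    """Percent identity over alignment columns, terminal gap columns excluded."""
    lo, hi = 0, len(row_a)
    while lo < hi and (row_a[lo] == "-" or row_b[lo] == "-"):
        lo += 1
    while hi > lo and (row_a[hi - 1] == "-" or row_b[hi - 1] == "-"):
        hi -= 1
    cols = hi - lo
    if cols == 0:
        return 0.0
    matches = sum(1 for i in range(lo, hi) if row_a[i] == row_b[i] and row_a[i] != "-")
    return 100.0 * matches / cols


def align_identity(a: str, b: str, mode: str = "global") -> float:
    """Raw percent identity of the optimal alignment of two sequences.

    Co-optimal alignments can differ in identity; the pair is aligned in a
    canonical (lexicographic) order so the result is symmetric in its
    arguments.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if b < a:
        a, b = b, a
    aln = _aligner(mode).align(a, b)[0]
    return _identity_from_rows(aln[0], aln[1])


def align_score_identity(a: str, b: str, mode: str = "global") -> tuple[float, float]:
    """Optimal alignment score and the identity of that alignment."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if b < a:
        a, b = b, a
    alns = _aligner(mode).align(a, b)
    aln = alns[0]
    return float(alns.score), _identity_from_rows(aln[0], aln[1])


def pairwise_identity(a: str, b: str, mode: str = "global",
                      id_a: str = "", id_b: str = "") -> PairIdentity:
    raw = align_identity(a, b, mode)
    return PairIdentity(id_a, id_b, raw, round_half_up(raw))


def unique_kmers(s: str, k: int = 8) -> frozenset[str]:
    """Distinct k-length words over {A,C,G,T}; windows with other letters skipped."""
    if k < 1:
        raise ValueError("k must be >= 1")
    words = set()
    valid = 0  # length of the current run of plain bases ending here
    for i, c in enumerate(s):
        valid = valid + 1 if c in "ACGT" else 0
        if valid >= k:
            words.add(s[i - k + 1: i + 1])
    return frozenset(words)


def top_hit(query: TaxSeqRecord, db: ReferenceDB, metric: str = "alignment",
            exclude_self: bool = False, mode: str = "global") -> Optional[TopHit]:
    """Best database record for a query; ties go to the earliest record.

    ``metric="alignment"`` maximizes alignment identity (global or local per
    ``mode``); ``metric="kmer"`` maximizes the number of shared unique
    eight-mers.  ``exclude_self`` masks the database record whose id equals
    the query id (record ids, not sequences, are compared).
    """
    if metric == "kmer":
        qwords = unique_kmers(query.sequence)
        best, best_score = None, -1.0
        for rec in db:
            if exclude_self and rec.id == query.id:
                continue
            score = len(qwords & unique_kmers(rec.sequence))
            if score > best_score:
                best, best_score = rec, score
        if best is None:
            return None
        raw = align_identity(query.sequence, best.sequence, "global")
        return TopHit(query.id, best.id, raw, round_half_up(raw), best_score)
    if metric != "alignment":
        raise ValueError(f"unknown metric {metric!r}")
    # global mode ranks hits by identity; local mode by alignment score, since
    # the identity of a short perfect local overlap is trivially 100%
    best, best_raw, best_key = None, -1.0, -float("inf")
    for rec in db:
        if exclude_self and rec.id == query.id:
            continue
        score, raw = align_score_identity(query.sequence, rec.sequence, mode)
        key = score if mode == "local" else raw
        if key > best_key:
            best, best_raw, best_key = rec, raw, key
    if best is None:
        return None
    return TopHit(query.id, best.id, best_raw, round_half_up(best_raw), best_key)


def all_pair_identities(db: ReferenceDB, mode: str = "global") -> list[PairIdentity]:
    """One entry per unordered distinct record pair (n(n-1)/2 entries)."""
    if len(db) < 2:
        raise ValueError("need at least two records")
    out = []
    for i in range(len(db)):
        for j in range(i + 1, len(db)):
            out.append(pairwise_identity(db[i].sequence, db[j].sequence, mode,
                                         db[i].id, db[j].id))
    return out


def identity_matrix(db: ReferenceDB, mode: str = "global") -> np.ndarray:
    """Symmetric n x n matrix of raw pairwise identities (diagonal 100).

    Computed once and shared by the split builder, split verifier and the
    alignment top-hit classifier, which all consult the same pairs.
    """
    n = len(db)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        si = db[i].sequence
        for j in range(i + 1, n):
            raw = align_identity(si, db[j].sequence, mode)
            mat[i, j] = mat[j, i] = raw
    return mat


def thid(queries: ReferenceDB, db: ReferenceDB, lcr_table=None,
         exclude_self: bool = False) -> ThidHistogram:
    """Top-hit identity distribution of a query set against a reference.

    With ``exclude_self`` and ``queries is db`` this is the nearest-neighbor
    identity distribution used for leave-one-out benchmarks.  When an LCR
    probability table is supplied, each occupied identity is annotated with
    its most probable lowest common rank.
    """
    if len(queries) == 0 or len(db) == 0:
        raise ValueError("queries and reference must be nonempty")
    counts: Counter[int] = Counter()
    for q in queries:
        hit = top_hit(q, db, metric="alignment", exclude_self=exclude_self)
        if hit is not None:
            counts[hit.identity_int] += 1
    annotations = None
    if lcr_table is not None:
        annotations = {}
        for d in counts:
            try:
                annotations[d] = lcr_table.mlr(d)
            except KeyError:
                annotations[d] = None
    return ThidHistogram(dict(counts), annotations)
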