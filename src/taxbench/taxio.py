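"""Taxonomy-annotated FASTA I/O, taxonomic lineages and reference preparation.

A reference database is a list of DNA sequences, each annotated with a
rank-ordered lineage (domain down to species, possibly truncated at a lower
rank).  Two header dialects are supported:

* ``sintax`` (canonical): ``>id;tax=d:Bacteria,p:Firmicutes,...,g:Foo;``
* ``lineage`` (Greengenes-style): ``>id k__Bacteria; p__Firmicutes; ...``

The module also provides the lowest-common-rank comparison between two
lineages, per-taxon subsampling and primer-based amplicon extraction.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

DEFAULT_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: IUPAC nucleotide codes and the plain bases each one matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class TaxFastaError(ValueError):
    """Malformed taxonomy-annotated FASTA input."""


@dataclass(frozen=True)
class RankOrder:
    """Ordered taxonomic ranks, highest (domain) to lowest (species).

    Rank comparisons throughout the package follow
    domain > phylum > class > order > family > genus > species;
    "lower" always means more specific.
    """

    ranks: tuple[str, ...] = DEFAULT_RANKS

    def __post_init__(self) -> None:
        if len(set(self.ranks)) != len(self.ranks) or not self.ranks:
            raise ValueError("rank labels must be unique and non-empty")
        if any(not r for r in self.ranks):
            raise ValueError("empty rank label")

    def __len__(self) -> int:
        return len(self.ranks)

    def __iter__(self) -> Iterator[str]:
        return iter(self.ranks)

    def __contains__(self, rank: str) -> bool:
        return rank in self.ranks

    def index(self, rank: str) -> int:
        """Position of ``rank``; 0 is the highest rank."""
        try:
            return self.ranks.index(rank)
        except ValueError:
            raise KeyError(f"unknown rank {rank!r}") from None

    def letter(self, rank: str) -> str:
        return rank[0]

    def rank_for_letter(self, letter: str) -> str:
        """Resolve a one-letter rank prefix (``k`` is accepted for domain)."""
        if letter == "k" and "domain" in self.ranks:
            return "domain"
        for r in self.ranks:
            if r[0] == letter:
                return r
        raise KeyError(f"unknown rank prefix {letter!r}")


@dataclass(frozen=True)
class Taxonomy:
    """A lineage: taxon names for a gapless leading run of the rank order.

    ``names[i]`` is the taxon at rank ``rank_order.ranks[i]``.  A lineage may
    be truncated (e.g., annotated only down to genus) but may not skip ranks.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if any(not n for n in self.names):
            raise ValueError("taxon names must be non-empty")

    @property
    def depth(self) -> int:
        return len(self.names)

    def name_at(self, rank: str, order: RankOrder) -> Optional[str]:
        i = order.index(rank)
        return self.names[i] if i < len(self.names) else None

    def truncate(self, rank: str, order: RankOrder) -> "Taxonomy":
        return Taxonomy(self.names[: order.index(rank) + 1])

    def as_dict(self, order: RankOrder) -> dict[str, str]:
        return dict(zip(order.ranks, self.names))


@dataclass(frozen=True)
class TaxSeqRecord:
    """A sequence with its identifier and taxonomy annotation."""

    id: str
    sequence: str
    taxonomy: Taxonomy

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")


class ReferenceDB:
    """An ordered collection of annotated sequences.

    Input order is preserved: several operations (top-hit searches and the
    split builder) break ties toward the earliest record.
    """

    def __init__(self, records: Iterable[TaxSeqRecord],
                 rank_order: RankOrder = RankOrder()):
        self.records: list[TaxSeqRecord] = list(records)
        self.rank_order = rank_order
        self._index: dict[str, int] = {}
        for i, rec in enumerate(self.records):
            if rec.id in self._index:
                raise TaxFastaError(f"duplicate record id {rec.id!r}")
            if rec.taxonomy.depth > len(rank_order):
                raise TaxFastaError(f"record {rec.id!r} has more ranks than the rank order")
            self._index[rec.id] = i

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TaxSeqRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> TaxSeqRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._index

    def get(self, rec_id: str) -> TaxSeqRecord:
        return self.records[self._index[rec_id]]

    def position(self, rec_id: str) -> int:
        return self._index[rec_id]

    def subset(self, ids: Iterable[str]) -> "ReferenceDB":
        """New db with the given records, in original input order."""
        keep = sorted(self._index[i] for i in ids)
        return ReferenceDB([self.records[i] for i in keep], self.rank_order)

    def names_at(self, rank: str) -> set[str]:
        """All taxon names present at ``rank``."""
        out = set()
        for rec in self.records:
            name = rec.taxonomy.name_at(rank, self.rank_order)
            if name is not None:
                out.add(name)
        return out


def lcr(a: Taxonomy, b: Taxonomy, rank_order: RankOrder = RankOrder()) -> Optional[str]:
    """Lowest common rank: the lowest rank at which both lineages share a name.

    Only ranks named in both lineages are compared; ``None`` is returned when
    no compared rank matches (downstream statistics treat this as a virtual
    rank above the highest named one).
    """
    depth = min(a.depth, b.depth)
    for i in range(depth - 1, -1, -1):
        if a.names[i] == b.names[i]:
            return rank_order.ranks[i]
    return None


# ---------------------------------------------------------------------------
# FASTA reading and writing

def _clean_sequence(raw: str, rec_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    if not seq:
        raise TaxFastaError(f"record {rec_id!r} has an empty sequence")
    return seq


def _parse_sintax_header(desc: str, order: RankOrder) -> tuple[str, Taxonomy]:
    rec_id = desc.split(";", 1)[0].split()[0]
    lo = desc.find("tax=")
    if lo < 0:
        raise TaxFastaError(f"record {rec_id!r}: header lacks 'tax=' annotation")
    body = desc[lo + 4:]
    hi = body.find(";")
    if hi >= 0:
        body = body[:hi]
    named: dict[int, str] = {}
    for part in body.split(","):
        part = part.strip()
        if not part:
            continue
        if ":" not in part:
            raise TaxFastaError(f"record {rec_id!r}: malformed lineage field {part!r}")
        letter, name = part.split(":", 1)
        try:
            rank = order.rank_for_letter(letter)
        except KeyError:
            raise TaxFastaError(
                f"record {rec_id!r}: rank prefix {letter!r} not in rank order") from None
        if not name:
            raise TaxFastaError(f"record {rec_id!r}: empty name at rank {rank!r}")
        named[order.index(rank)] = name.strip()
    return rec_id, _lineage_from_sparse(named, rec_id, order)


def _parse_lineage_header(desc: str, order: RankOrder) -> tuple[str, Taxonomy]:
    fields = desc.split(None, 1)
    rec_id = fields[0]
    if len(fields) < 2:
        raise TaxFastaError(f"record {rec_id!r}: header lacks a lineage annotation")
    named: dict[int, str] = {}
    for part in fields[1].split(";"):
        part = part.strip()
        if not part:
            continue
        if "__" not in part:
            raise TaxFastaError(f"record {rec_id!r}: malformed lineage field {part!r}")
        letter, name = part.split("__", 1)
        name = name.strip()
        if not name:  # empty slot, e.g. "s__" -- lineage truncated here
            continue
        try:
            rank = order.rank_for_letter(letter)
        except KeyError:
            raise TaxFastaError(
                f"record {rec_id!r}: rank prefix {letter!r} not in rank order") from None
        named[order.index(rank)] = name
    return rec_id, _lineage_from_sparse(named, rec_id, order)


def _lineage_from_sparse(named: dict[int, str], rec_id: str, order: RankOrder) -> Taxonomy:
    if not named:
        raise TaxFastaError(f"record {rec_id!r}: empty lineage")
    depth = max(named) + 1
    if sorted(named) != list(range(depth)):
        missing = [order.ranks[i] for i in range(depth) if i not in named]
        raise TaxFastaError(
            f"record {rec_id!r}: lineage gap, unnamed rank(s) {missing} above a named rank")
    return Taxonomy(tuple(named[i] for i in range(depth)))


def read_tax_fasta(path, dialect: str = "sintax",
                   rank_order: RankOrder = RankOrder()) -> ReferenceDB:
    """Read an annotated FASTA file (plain or gzip) into a :class:`ReferenceDB`."""
    if dialect not in ("sintax", "lineage"):
        raise ValueError(f"unknown dialect {dialect!r}")
    parse = _parse_sintax_header if dialect == "sintax" else _parse_lineage_header
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records = []
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            rec_id, taxonomy = parse(rec.description, rank_order)
            records.append(TaxSeqRecord(rec_id, _clean_sequence(str(rec.seq), rec_id), taxonomy))
    return ReferenceDB(records, rank_order)


def format_sintax_header(rec: TaxSeqRecord, order: RankOrder) -> str:
    parts = ",".join(
        f"{order.letter(order.ranks[i])}:{name}" for i, name in enumerate(rec.taxonomy.names)
    )
    return f"{rec.id};tax={parts};"


def write_tax_fasta(db: ReferenceDB, path) -> None:
    """Write a reference in the sintax header dialect, one sequence line per record."""
    if len(db) == 0:
        raise TaxFastaError("refusing to write an empty reference")
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as out:
        for rec in db:
            out.write(f">{format_sintax_header(rec, db.rank_order)}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# Reference preparation

def subsample_by_taxon(db: ReferenceDB, rank: str, cap: int, seed: int) -> ReferenceDB:
    """Retain at most ``cap`` records per taxon at ``rank``, discarding at random.

    Records lacking a name at ``rank`` are always retained.  Survivors keep
    their relative input order and are unmodified; the same seed reproduces
    the same subset.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    db.rank_order.index(rank)  # raises KeyError for unknown rank
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(db):
        name = rec.taxonomy.name_at(rank, db.rank_order)
        if name is not None:
            groups.setdefault(name, []).append(i)
    rng = np.random.default_rng(seed)
    drop: set[int] = set()
    for name in sorted(groups):
        idxs = groups[name]
        if len(idxs) > cap:
            keep = rng.choice(len(idxs), size=cap, replace=False)
            kept = {idxs[k] for k in keep}
            drop.update(i for i in idxs if i not in kept)
    return ReferenceDB([r for i, r in enumerate(db) if i not in drop], db.rank_order)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _find_primer(seq: str, primer: str, max_mismatch: int) -> Optional[int]:
    """Leftmost position where ``primer`` matches with <= ``max_mismatch`` mismatches.

    Degenerate letters in the primer match their IUPAC expansion; degenerate
    letters in the sequence match nothing (they count as mismatches).
    """
    psets = [IUPAC.get(c, "") for c in primer]
    plen = len(primer)
    for start in range(len(seq) - plen + 1):
        mism = 0
        for j in range(plen):
            base = seq[start + j]
            if base not in "ACGT" or base not in psets[j]:
                mism += 1
                if mism > max_mismatch:
                    break
        if mism <= max_mismatch:
            return start
    return None


def _extract_one(seq: str, fwd: str, rev_rc: str, max_mismatch: int) -> tuple[Optional[str], str]:
    """Inter-primer segment of one strand, or (None, reason)."""
    f = _find_primer(seq, fwd, max_mismatch)
    if f is None:
        return None, "fwd_primer_not_found"
    tail_start = f + len(fwd)
    r = _find_primer(seq[tail_start:], rev_rc, max_mismatch)
    if r is None:
        return None, "rev_primer_not_found"
    segment = seq[tail_start: tail_start + r]
    if not segment:
        return None, "empty_amplicon"
    return segment, ""


def extract_amplicon(db: ReferenceDB, fwd_primer: str, rev_primer: str,
                     max_mismatch: int = 2) -> tuple[ReferenceDB, list[tuple[str, str]]]:
    """Extract the segment between two PCR primers from every record.

    The forward primer and the reverse complement of the reverse primer are
    located with at most ``max_mismatch`` mismatches each; the emitted segment
    excludes both primer sites.  The forward strand is scanned first; when no
    hit pair exists there, the record's reverse complement is scanned and the
    segment is re-oriented to forward.  Records lacking both sites are dropped.

    Returns the trimmed reference and a drop log of ``(record id, reason)``.
    """
    if min(len(fwd_primer), len(rev_primer)) < 10:
        raise ValueError("primers must be at least 10 nt")
    rev_rc = reverse_complement(rev_primer.upper())
    fwd = fwd_primer.upper()
    kept, drops = [], []
    for rec in db:
        segment, reason = _extract_one(rec.sequence, fwd, rev_rc, max_mismatch)
        if segment is None:
            segment, _ = _extract_one(reverse_complement(rec.sequence), fwd, rev_rc, max_mismatch)
        if segment is None:
            drops.append((rec.id, reason))
        else:
            kept.append(TaxSeqRecord(rec.id, segment, rec.taxonomy))
    if not kept:
        logger.warning("amplicon extraction found no primer sites in any record")
    elif drops:
        logger.info("amplicon extraction dropped %d/%d records", len(drops), len(db))
    return ReferenceDB(kept, db.rank_order), drops


def write_drop_log(drops: list[tuple[str, str]], path) -> None:
    with open(path, "w") as out:
        for rec_id, reason in drops:
            out.write(f"{rec_id}\t{reason}\n")
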