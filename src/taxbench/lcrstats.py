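"""Lowest-common-rank probability statistics.

From the all-vs-all pairwise identities of an annotated reference this module
builds the conditional distribution P(LCR = r | d): the probability that a
pair of sequences drawn from the reference with integer identity d has rank r
as its lowest shared rank.  Derived quantities:

* P_CR(r | d): probability the pair shares a name at rank r or below,
  i.e. the cumulative sum of P(LCR = s | d) over ranks s at or below r.
* MLR(d): the most probable lowest common rank at identity d.
* RIT(r): rank identity threshold, the minimum identity whose MLR is r.
* Known/novel OTU estimates from a top-hit identity distribution:
  K_d(r) = P_CR(r | d) * N_d known and L_d(r) = (1 - P_CR(r | d)) * N_d novel
  OTUs at identity d, summed over identities for totals.

Pairs sharing no rank at all carry probability mass under a virtual rank
("NONE") that sits above the highest named rank: it appears in the
denominator of P(LCR = r | d) but is excluded from P_CR and never returned
as an MLR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._util import round_half_up
from .identity import ThidHistogram, identity_matrix
from .taxio import RankOrder, ReferenceDB, lcr

logger = logging.getLogger(__name__)

#: Dictionary key and output label for the virtual no-common-rank outcome.
NONE_RANK = None
WEAK_ROW_FLOOR = 10  # rows with fewer pairs are flagged as statistically weak


class LcrTable:
    """Per-identity pair counts and LCR probabilities.

    ``counts[d][r]`` is the number of pairs with integer identity ``d`` whose
    lowest common rank is ``r`` (``None`` for no shared rank).  Identities
    with no pairs are simply absent.
    """

    def __init__(self, counts: dict[int, dict[Optional[str], int]],
                 rank_order: RankOrder = RankOrder()):
        self.rank_order = rank_order
        self.counts = {
            int(d): {r: int(c) for r, c in row.items() if c}
            for d, row in counts.items() if sum(row.values())
        }
        for d, row in self.counts.items():
            for r in row:
                if r is not NONE_RANK and r not in rank_order:
                    raise KeyError(f"unknown rank {r!r} at d={d}")
        weak = [d for d, row in self.counts.items() if sum(row.values()) < WEAK_ROW_FLOOR]
        if weak:
            logger.warning("LCR table rows with fewer than %d pairs (statistically weak): %s",
                           WEAK_ROW_FLOOR, sorted(weak))

    @classmethod
    def from_counts(cls, counts, rank_order: RankOrder = RankOrder()) -> "LcrTable":
        return cls(counts, rank_order)

    def occupied(self) -> list[int]:
        return sorted(self.counts)

    def total_pairs(self, d: int) -> int:
        """M_d: number of pairs at integer identity d."""
        return sum(self.counts[d].values())

    def _row(self, d: int) -> dict[Optional[str], int]:
        if d not in self.counts:
            raise KeyError(f"no pairs observed at identity {d}")
        return self.counts[d]

    def p(self, rank: Optional[str], d: int) -> float:
        """P(LCR = rank | d), including the virtual NONE rank."""
        row = self._row(d)
        return row.get(rank, 0) / sum(row.values())

    def p_cr(self, rank: str, d: int) -> float:
        """P_CR(rank | d): probability of a shared name at ``rank`` or below."""
        row = self._row(d)
        lo = self.rank_order.index(rank)
        m = sum(c for r, c in row.items()
                if r is not NONE_RANK and self.rank_order.index(r) >= lo)
        return m / sum(row.values())

    def mlr(self, d: int) -> Optional[str]:
        """Most probable LCR at identity d; ties break to the lower rank.

        NONE is never returned; if all pairs at d share no rank the result is
        ``None`` meaning "no named rank" (such rows never define thresholds).
        """
        row = self._row(d)
        best, best_count = None, 0
        for r in reversed(self.rank_order.ranks):  # species first: ties stay low
            if row.get(r, 0) > best_count:
                best, best_count = r, row[r]
        return best

    def rit(self) -> dict[str, int]:
        """Rank identity thresholds: min{d : MLR(d) = r} per rank.

        Ranks that are never the most probable LCR are absent from the result.
        """
        out: dict[str, int] = {}
        for d in self.occupied():
            r = self.mlr(d)
            if r is not None and r not in out:
                out[r] = d
        # min over d, so first occurrence in ascending order wins
        return out

    def p_cr_interpolated(self, rank: str, d: int) -> float:
        """P_CR at d, linearly interpolated from the nearest occupied rows.

        Outside the occupied range the value is clamped to the nearest row.
        """
        if d in self.counts:
            return self.p_cr(rank, d)
        ds = self.occupied()
        if not ds:
            raise ValueError("empty LCR table")
        below = [x for x in ds if x < d]
        above = [x for x in ds if x > d]
        if not below:
            logger.info("identity %d below table range; clamping to %d", d, ds[0])
            return self.p_cr(rank, ds[0])
        if not above:
            logger.info("identity %d above table range; clamping to %d", d, ds[-1])
            return self.p_cr(rank, ds[-1])
        d0, d1 = max(below), min(above)
        p0, p1 = self.p_cr(rank, d0), self.p_cr(rank, d1)
        logger.info("identity %d absent from table; interpolating between %d and %d", d, d0, d1)
        return p0 + (p1 - p0) * (d - d0) / (d1 - d0)

    def to_tsv(self, path) -> None:
        """Counts and probabilities, one row per occupied identity."""
        ranks = list(self.rank_order.ranks) + ["NONE"]
        with open(path, "w") as out:
            out.write("d\tM_d\t" + "\t".join(f"m_{r}" for r in ranks)
                      + "\t" + "\t".join(f"P_{r}" for r in ranks) + "\n")
            for d in sorted(self.counts, reverse=True):
                row = self.counts[d]
                m_d = sum(row.values())
                ms = [row.get(r if r != "NONE" else NONE_RANK, 0) for r in ranks]
                out.write(f"{d}\t{m_d}\t" + "\t".join(str(m) for m in ms)
                          + "\t" + "\t".join(f"{m / m_d:.4f}" for m in ms) + "\n")

    def write_mlr_tsv(self, path) -> None:
        """Per-identity cumulative probabilities and the most probable LCR."""
        ranks = self.rank_order.ranks
        with open(path, "w") as out:
            out.write("d\t" + "\t".join(f"Pcr_{r}" for r in ranks) + "\tMLR\n")
            for d in sorted(self.counts, reverse=True):
                pcrs = [f"{self.p_cr(r, d):.4f}" for r in ranks]
                out.write(f"{d}\t" + "\t".join(pcrs) + f"\t{self.mlr(d) or 'NA'}\n")

    def write_rit_tsv(self, path) -> None:
        rit = self.rit()
        with open(path, "w") as out:
            out.write("rank\tRIT\n")
            for r in self.rank_order:
                out.write(f"{r}\t{rit.get(r, 'NA')}\n")


def lcr_table(db: ReferenceDB, mode: str = "global",
              identities: Optional[np.ndarray] = None) -> LcrTable:
    """Build the LCR probability table from all unordered distinct pairs.

    Pairs are distinct (no self-pairs): a self-pair always has LCR equal to
    its own lowest rank at 100% identity and would only inject artificial
    lowest-rank mass into the d=100 row.
    """
    n = len(db)
    if n < 2:
        raise ValueError("need at least two records")
    if identities is None:
        identities = identity_matrix(db, mode)
    order = db.rank_order
    counts: dict[int, dict[Optional[str], int]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = round_half_up(identities[i, j])
            r = lcr(db[i].taxonomy, db[j].taxonomy, order)
            row = counts.setdefault(d, {})
            row[r] = row.get(r, 0) + 1
    return LcrTable(counts, order)


def common_rank_prob(table: LcrTable, rank: str, d: int) -> float:
    """P_CR(rank | d) for an occupied identity row."""
    return table.p_cr(rank, d)


def mlr(table: LcrTable, d: int) -> Optional[str]:
    """Most probable lowest common rank at identity d."""
    return table.mlr(d)


def rank_identity_thresholds(table: LcrTable) -> dict[str, int]:
    """RIT(r) per rank; ranks with no threshold are absent."""
    return table.rit()


@dataclass
class KnownNovelEstimate:
    """Estimated known and novel OTU counts at one rank.

    ``per_d`` maps each occupied top-hit identity to its (known, novel)
    contribution; ``known`` and ``novel`` are the totals over identities.
    """

    rank: str
    per_d: dict[int, tuple[float, float]] = field(default_factory=dict)

    @property
    def known(self) -> float:
        return sum(k for k, _ in self.per_d.values())

    @property
    def novel(self) -> float:
        return sum(v for _, v in self.per_d.values())

    def to_tsv(self, path) -> None:
        with open(path, "w") as out:
            out.write("d\tN_d\tK_est\tL_est\n")
            for d in sorted(self.per_d, reverse=True):
                k, v = self.per_d[d]
                out.write(f"{d}\t{k + v:.0f}\t{k:.2f}\t{v:.2f}\n")
            out.write(f"total\t{self.known + self.novel:.0f}\t"
                      f"{self.known:.2f}\t{self.novel:.2f}\n")


def estimate_known_novel(thid_hist: ThidHistogram, table: LcrTable,
                         rank: str) -> KnownNovelEstimate:
    """Estimate how many OTUs belong to known vs. novel taxa at ``rank``.

    For each occupied top-hit identity d with N_d OTUs, the expected number
    whose taxon at ``rank`` is present in the reference is P_CR(rank|d)*N_d
    and the remainder is novel.  Identities absent from the table use
    linearly interpolated (range-clamped) probabilities.
    """
    est = KnownNovelEstimate(rank)
    for d, n_d in sorted(thid_hist.counts.items()):
        p = table.p_cr_interpolated(rank, d)
        est.per_d[d] = (p * n_d, (1.0 - p) * n_d)
    return est
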