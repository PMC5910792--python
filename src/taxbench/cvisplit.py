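"""Identity-constrained cross-validation splits and leave-one-out pairs.

For a chosen top-hit identity d, a reference R is partitioned into four
disjoint subsets: the test set S, its in-range top hits T, additional
training sequences W whose identity to every test sequence is below d, and a
discard pile Z of sequences that would violate the constraint in any other
subset.  The training set is A = T ∪ W, and by construction the top training
hit of every test sequence lies in [d - δ, d + δ].

The builder is a best-effort greedy (maximize |S| first, then salvage W);
no optimality is claimed, and :func:`verify_split` re-checks the constraint
by realignment, which is the actual contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from ._util import derive_seed
from .identity import identity_matrix
from .taxio import ReferenceDB, TaxSeqRecord

logger = logging.getLogger(__name__)

#: Benchmark defaults: target top-hit identities and allowed deviations.
DEFAULT_D_VALUES = (100.0, 99.0, 97.0, 95.0, 90.0)
DEFAULT_DELTAS = {100.0: 0.0, 99.0: 0.5, 97.0: 0.5, 95.0: 0.5, 90.0: 1.0}

_EPS = 1e-9  # guard against float noise at the interval edges


def default_delta(d: float) -> float:
    return DEFAULT_DELTAS.get(float(d), 0.5 if d > 92 else 1.0)


@dataclass(frozen=True)
class SplitSpec:
    """Target top-hit identity d, allowed deviation delta, and shuffle seed."""

    d: float
    delta: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.d <= 100:
            raise ValueError("d must be in (0, 100]")
        if self.delta is None:
            object.__setattr__(self, "delta", default_delta(self.d))
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


def default_specs(seed: int = 0) -> list[SplitSpec]:
    return [SplitSpec(d, DEFAULT_DELTAS[d], derive_seed(seed, "split", d))
            for d in DEFAULT_D_VALUES]


@dataclass
class SplitResult:
    """The four subsets of a reference for one (d, delta).

    S/T/W/Z partition the reference ids, except in the degenerate d=100 case
    where S = T = R and W = Z are empty (test and training both equal R).
    """

    S: frozenset[str]
    T: frozenset[str]
    W: frozenset[str]
    Z: frozenset[str]
    spec: SplitSpec

    @property
    def training(self) -> frozenset[str]:
        """A = T ∪ W."""
        return self.T | self.W

    def subset_of(self, rec_id: str) -> str:
        for label in "STWZ":
            if rec_id in getattr(self, label):
                return label
        raise KeyError(rec_id)

    def write_manifest(self, path) -> None:
        with open(path, "w") as out:
            out.write("id\tsubset\n")
            for label in "STWZ":
                for rec_id in sorted(getattr(self, label)):
                    out.write(f"{rec_id}\t{label}\n")


@dataclass
class SplitReport:
    ok: bool
    violations: list[str] = field(default_factory=list)


def build_split(db: ReferenceDB, spec: SplitSpec,
                identities: Optional[np.ndarray] = None) -> SplitResult:
    """Greedy construction of a verified test/training split.

    Candidates are visited in seeded-shuffled order.  A candidate q joins S
    when some eligible record t has raw identity to q within [d-δ, d+δ] and
    no committed training member exceeds d+δ with q; the in-range t closest
    to d (ties to the earlier record) joins T, and every record closer than
    d+δ to q is barred from the training set.  Leftover records go to W when
    their identity to every test sequence is below d, otherwise to Z.
    """
    n = len(db)
    d, delta = spec.d, spec.delta
    if d == 100.0:
        ids = frozenset(db.ids)
        return SplitResult(ids, ids, frozenset(), frozenset(), spec)
    if n < 2:
        raise ValueError("need at least two records for d < 100")
    if identities is None:
        identities = identity_matrix(db)

    lo, hi = d - delta - _EPS, d + delta + _EPS
    in_s = np.zeros(n, dtype=bool)
    in_t = np.zeros(n, dtype=bool)
    forbidden = np.zeros(n, dtype=bool)  # barred from the training set

    rng = np.random.default_rng(spec.seed)
    for q in rng.permutation(n):
        if in_s[q] or in_t[q]:
            continue
        row = identities[q]
        committed = in_t & (np.arange(n) != q)
        if np.any(row[committed] > hi):
            continue  # an existing training member is too close to q
        eligible = ~in_s & ~forbidden & (np.arange(n) != q)
        candidates = np.flatnonzero(eligible & (row >= lo) & (row <= hi))
        if candidates.size == 0:
            continue
        t = candidates[np.argmin(np.abs(row[candidates] - d))]
        in_s[q] = True
        in_t[t] = True
        forbidden |= (row > hi) & ~in_s
        forbidden[q] = True

    s_idx = np.flatnonzero(in_s)
    w, z = [], []
    for x in np.flatnonzero(~in_s & ~in_t):
        if forbidden[x]:
            z.append(x)
        elif s_idx.size == 0 or identities[x, s_idx].max() < d:
            w.append(x)
        else:
            z.append(x)

    if s_idx.size == 0:
        logger.warning("no admissible test/training pair at d=%.1f +/- %.1f; empty test set",
                       d, delta)
    ids = db.ids
    return SplitResult(
        frozenset(ids[i] for i in s_idx),
        frozenset(ids[i] for i in np.flatnonzero(in_t)),
        frozenset(ids[i] for i in w),
        frozenset(ids[i] for i in z),
        spec,
    )


def verify_split(db: ReferenceDB, result: SplitResult,
                 identities: Optional[np.ndarray] = None) -> SplitReport:
    """Independently re-check a split against its identity constraint.

    Recomputes, for every test sequence, the raw identity of its top training
    hit and reports any value outside [d - δ, d + δ], along with any breach
    of the partition invariants.  Violations are reported, not raised.
    """
    violations: list[str] = []
    d, delta = result.spec.d, result.spec.delta
    all_ids = set(db.ids)
    degenerate = d == 100.0 and result.S == result.T

    union = result.S | result.T | result.W | result.Z
    if union != all_ids:
        missing = sorted(all_ids - union)[:5]
        extra = sorted(union - all_ids)[:5]
        violations.append(f"subsets do not cover the reference (missing={missing}, extra={extra})")
    if not degenerate:
        for a, b in (("S", "T"), ("S", "W"), ("S", "Z"), ("T", "W"), ("T", "Z"), ("W", "Z")):
            overlap = getattr(result, a) & getattr(result, b)
            if overlap:
                violations.append(f"subsets {a} and {b} overlap: {sorted(overlap)[:5]}")

    training = sorted(result.training & all_ids)
    if result.S and not training:
        violations.append("test set is nonempty but training set is empty")
    elif result.S:
        if identities is None:
            identities = identity_matrix(db)
        t_idx = np.array([db.position(i) for i in training])
        for s in sorted(result.S):
            si = db.position(s)
            cols = t_idx if degenerate else t_idx[t_idx != si]
            top = float(identities[si, cols].max())
            if not (d - delta - _EPS <= top <= d + delta + _EPS):
                offender = training[int(np.argmax(identities[si, t_idx]))]
                violations.append(
                    f"test {s}: top training hit {offender} at {top:.2f}%% "
                    f"outside [{d - delta:.2f}, {d + delta:.2f}]")
    return SplitReport(ok=not violations, violations=violations)


class MaskedDB:
    """Read-only view of a reference with one record masked out by id."""

    def __init__(self, db: ReferenceDB, excluded_id: str):
        self._db = db
        self.excluded_id = excluded_id
        self.rank_order = db.rank_order

    def __len__(self) -> int:
        return len(self._db) - (1 if self.excluded_id in self._db else 0)

    def __iter__(self) -> Iterator[TaxSeqRecord]:
        return (r for r in self._db if r.id != self.excluded_id)

    def get(self, rec_id: str) -> TaxSeqRecord:
        if rec_id == self.excluded_id:
            raise KeyError(f"record {rec_id!r} is masked out")
        return self._db.get(rec_id)

    def names_at(self, rank: str) -> set[str]:
        out = set()
        for rec in self:
            name = rec.taxonomy.name_at(rank, self.rank_order)
            if name is not None:
                out.add(name)
        return out


def l1o_pairs(db: ReferenceDB) -> Iterator[tuple[TaxSeqRecord, MaskedDB]]:
    """Leave-one-out evaluation pairs: each record vs. the rest of the db.

    Training sets are lazy id-masked views, not copies; exactly ``len(db)``
    pairs are yielded.
    """
    if len(db) < 2:
        raise ValueError("need at least two records for leave-one-out")
    for rec in db:
        yield rec, MaskedDB(db, rec.id)
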