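"""Shared fixtures: tiny hand-built references and simulated databases.

The expensive session fixtures (simulated references and their all-vs-all
identity matrices) are shared across test modules to keep the suite fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from taxbench import (RankOrder, ReferenceDB, SimConfig, TaxSeqRecord, Taxonomy,
                      identity_matrix, simulate_reference)

ORDER = RankOrder()


def rec(rec_id: str, seq: str, *names: str) -> TaxSeqRecord:
    return TaxSeqRecord(rec_id, seq, Taxonomy(tuple(names)))


def full_lineage(genus: str, species: str | None = None, family: str = "F1",
                 order: str = "O1", cls: str = "C1", phylum: str = "P1",
                 domain: str = "Bacteria") -> tuple[str, ...]:
    names = (domain, phylum, cls, order, family, genus)
    return names + (species,) if species else names


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A compact simulated reference: quick to align all-vs-all."""
    return SimConfig(
        branching={"phylum": 2, "class": 2, "order": 2, "family": 2,
                   "genus": (1, 3), "species": (1, 2)},
        seqs_per_species=(1, 2),
        seq_length=150,
        seed=2024,
    )


@pytest.fixture(scope="session")
def small_db(small_cfg) -> ReferenceDB:
    return simulate_reference(small_cfg)


@pytest.fixture(scope="session")
def small_matrix(small_db) -> np.ndarray:
    return identity_matrix(small_db)


@pytest.fixture(scope="session")
def default_db() -> ReferenceDB:
    """The benchmark-scale reference under the generator's default conditions."""
    return simulate_reference(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_matrix(default_db) -> np.ndarray:
    return identity_matrix(default_db)
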