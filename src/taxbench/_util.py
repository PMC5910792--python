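"""Small shared helpers."""

from __future__ import annotations

import hashlib
import math


def round_half_up(x: float) -> int:
    """Integer rounding with halves rounded up (87.5 -> 88)."""
    return int(math.floor(x + 0.5))


def derive_seed(seed: int, *tokens) -> int:
    """Stable sub-seed from a top-level seed and a sequence of tokens.

    Used so that every randomized stage (simulation, splitting, per-query
    bootstraps) has its own independent stream while remaining reproducible
    and order-independent.
    """
    h = hashlib.sha256(repr((int(seed),) + tokens).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)
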