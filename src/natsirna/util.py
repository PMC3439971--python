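"""Shared helpers: interval arithmetic, sequence ops, seeded substreams, rounding."""

from __future__ import annotations

import zlib
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def overlap_interval(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int] | None:
    """Intersection of two half-open intervals, or None if disjoint."""
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    return (lo, hi) if lo < hi else None


def interval_len(iv: tuple[int, int]) -> int:
    return iv[1] - iv[0]


def contains(outer: tuple[int, int], inner: tuple[int, int]) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG of a master seed.

    The name is hashed with CRC32 so each pipeline stage draws from an
    independent stream regardless of the order stages run in.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=(zlib.crc32(name.encode()),))
    )


def pct_half_up(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage rounded half-up to the given decimals (report style: 84/1374 -> 6.1)."""
    if denominator == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(q, rounding=ROUND_HALF_UP)
    )


def signed_ratio(r: float) -> float:
    """Fold-change ratio expressed as a signed value with magnitude >= 1.

    r >= 1 maps to +r (up in treatment); r < 1 maps to -1/r (down).
    """
    if r <= 0:
        raise ValueError("ratio must be positive")
    return r if r >= 1 else -1.0 / r
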