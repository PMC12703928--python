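"""Brute-force rank oracles and seeded synthetic inputs.

The oracles are deliberately naive linear scans, kept independent of the
directory-based structures they validate.  Generators use numpy's
``default_rng`` (PCG64) so identical specs reproduce identical data on
every platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import AlphabetError, RangeError


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic description of one synthetic input.

    ``sigma is None`` yields a bit vector with 1-probability ``density``;
    otherwise a text of symbols drawn uniformly from ``[0, sigma)``.
    """

    seed: int
    n: int
    density: float = 0.5
    sigma: Optional[int] = None


def generate(spec: FixtureSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    if spec.sigma is not None:
        return rng.integers(0, spec.sigma, size=spec.n, dtype=np.int64).astype(np.uint8)
    return (rng.random(spec.n) < spec.density).astype(np.uint8)


def random_bits(seed: int, n: int, density: float = 0.5) -> np.ndarray:
    return generate(FixtureSpec(seed=seed, n=n, density=density))


def random_text(seed: int, n: int, sigma: int) -> np.ndarray:
    return generate(FixtureSpec(seed=seed, n=n, sigma=sigma))


def oracle_rank_bits(bits, i: int) -> int:
    """Linear-scan prefix sum over a 0/1 array."""
    bits = np.asarray(bits)
    if not 0 <= i <= bits.size:
        raise RangeError(f"rank position {i} outside [0, {bits.size}]")
    return int(np.sum(bits[:i], dtype=np.int64))


def oracle_rank_text(symbols, i: int, c: int) -> int:
    """Linear-scan count of code ``c`` among the first ``i`` symbols."""
    symbols = np.asarray(symbols)
    if not 0 <= i <= symbols.size:
        raise RangeError(f"rank position {i} outside [0, {symbols.size}]")
    if c < 0:
        raise AlphabetError("negative symbol code")
    return int(np.sum(symbols[:i] == c, dtype=np.int64))


def oracle_rank_bits_all(bits) -> np.ndarray:
    """rank(i) for every i in [0, n], as one cumulative-sum pass."""
    bits = np.asarray(bits, dtype=np.int64)
    out = np.zeros(bits.size + 1, dtype=np.int64)
    np.cumsum(bits, out=out[1:])
    return out


def oracle_rank_text_all(symbols, c: int) -> np.ndarray:
    """rank(i, c) for every i in [0, n]."""
    return oracle_rank_bits_all(np.asarray(symbols) == c)
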