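"""Bit vectors with O(1) rank in four directory layouts.

Layouts: single- or two-layer directories, each either conventional
(one entry per block / superblock, prefix sums) or *paired* (one entry
per block pair / superblock pair, half the entries).  In paired layouts a
query in the left member of a pair subtracts a suffix count from an
over-counting directory entry; a query in the right member adds a prefix
count, exactly as in the non-paired case.

Two-layer paired directories store, per block pair p:

* right superblock: prefix count from the superblock-pair's right
  superblock start through the end of p's left block;
* left superblock: postfix count from the end of p's left block to the
  end of the left superblock (the amount the superblock-pair L0 entry
  over-counts by).

The L0 entry of superblock pair q is the absolute prefix count through
the end of q's *left* superblock.  rank(i) then evaluates as
``L0[q] + s1*L1[p] + s2*c`` with ``s1 = +1`` iff i falls in a right
superblock and ``s2 = +1`` iff i falls in a right block, c being the
block prefix/suffix count from the configured strategy.

The bit layer is zero-padded to a whole number of superblocks
(non-paired) or superblock pairs (paired), so every left member has a
right partner and every pair has a directory entry.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .core_bits import (
    SUPPORTED_BLOCK_BITS,
    WORD_BITS,
    PackedBits,
    _ceil_div,
    _vec_count,
    make_mask_table,
)
from .errors import ConfigError, FormatError, RangeError
from .report import StorageReport

L1_ENTRY_BITS = 16
L0_ENTRY_BITS = 64

_U64 = np.uint64

_STRATEGIES = ("mask", "shift")


@dataclass(frozen=True)
class RankConfig:
    """Structure parameters for a rank directory."""

    block_bits: int = 512
    superblock_bits: int = 65536
    paired: bool = False
    layers: int = 2
    strategy: str = "mask"

    def __post_init__(self):
        if self.block_bits not in SUPPORTED_BLOCK_BITS:
            raise ConfigError(f"block_bits must be one of {SUPPORTED_BLOCK_BITS}")
        if self.layers not in (1, 2):
            raise ConfigError("layers must be 1 or 2")
        if self.strategy not in _STRATEGIES:
            raise ConfigError(f"strategy must be one of {_STRATEGIES}")
        if self.layers == 2:
            if self.superblock_bits % self.block_bits:
                raise ConfigError("superblock_bits must be a multiple of block_bits")
            if self.paired and self.superblock_bits % (2 * self.block_bits):
                raise ConfigError("paired layouts need superblock_bits divisible by 2*block_bits")
            if self.superblock_bits - self.block_bits >= 1 << L1_ENTRY_BITS:
                raise ConfigError("superblock_bits too large for 16-bit L1 entries")

    @property
    def span_bits(self) -> int:
        """Padding granularity of the bit layer."""
        unit = self.superblock_bits if self.layers == 2 else self.block_bits
        return 2 * unit if self.paired else unit

    def padded_bits(self, n: int) -> int:
        return _ceil_div(n, self.span_bits) * self.span_bits if n else 0

    def l1_entries(self, n: int) -> int:
        if self.layers == 1:
            return 0
        padded = self.padded_bits(n)
        return padded // (2 * self.block_bits) if self.paired else padded // self.block_bits

    def l0_entries(self, n: int) -> int:
        padded = self.padded_bits(n)
        if self.layers == 1:
            return padded // (2 * self.block_bits) if self.paired else padded // self.block_bits
        return padded // (2 * self.superblock_bits) if self.paired else padded // self.superblock_bits


@dataclass(frozen=True)
class RankDirectory:
    """Flat L0 (64-bit absolute) and L1 (16-bit relative) count arrays."""

    L0: np.ndarray
    L1: Optional[np.ndarray] = None

    @property
    def l0_bits(self) -> int:
        return L0_ENTRY_BITS * self.L0.size

    @property
    def l1_bits(self) -> int:
        return 0 if self.L1 is None else L1_ENTRY_BITS * self.L1.size


@dataclass(frozen=True)
class QueryCursor:
    """Decomposition of a query prefix length into directory coordinates."""

    i: int
    i_b: int
    i_l1: int
    i_l0: int
    pos: int
    block_side: str
    superblock_side: str


def query_cursor(config: RankConfig, i: int) -> QueryCursor:
    w1 = config.block_bits
    i_b = i // w1
    if config.paired:
        i_l1 = i // (2 * w1)
        pos = i - i_l1 * 2 * w1
        block_side = "left" if pos < w1 else "right"
        if config.layers == 2:
            w0 = config.superblock_bits
            i_l0 = i // (2 * w0)
            superblock_side = "left" if (i // w0) % 2 == 0 else "right"
        else:
            i_l0 = i_l1
            superblock_side = block_side
    else:
        i_l1 = i_b
        pos = w1 + (i - i_b * w1)
        block_side = "right"
        superblock_side = "right"
        i_l0 = i // config.superblock_bits if config.layers == 2 else i_b
    return QueryCursor(i, i_b, i_l1, i_l0, pos, block_side, superblock_side)


def _query_parts(config: RankConfig, j: np.ndarray):
    """Vectorized block coordinates: (block index, pair offset, block sign)."""
    w1 = config.block_bits
    if config.paired:
        p = j // (2 * w1)
        pos = j - p * (2 * w1)
        right = pos >= w1
        bidx = 2 * p + right
        s2 = np.where(right, 1, -1)
        return bidx, p, pos, s2
    bidx = j // w1
    ppos = w1 + (j - bidx * w1)
    return bidx, bidx, ppos, np.ones_like(j)


class RankBitVector:
    """A bit vector plus its rank directory."""

    __slots__ = ("bits", "config", "dir", "ones_total")

    def __init__(self, bits: PackedBits, config: RankConfig, directory: RankDirectory, ones_total: int):
        self.bits = bits
        self.config = config
        self.dir = directory
        self.ones_total = int(ones_total)

    @property
    def n(self) -> int:
        return self.bits.length_bits

    @property
    def padded_bits(self) -> int:
        return self.bits.padded_bits

    def __len__(self) -> int:
        return self.n

    # -- queries ------------------------------------------------------------

    def rank(self, i) -> "int | np.ndarray":
        """Number of set bits among the first ``i`` positions, i in [0, n].

        Accepts a scalar or an integer array (evaluated vectorized).
        """
        arr = np.asarray(i, dtype=np.int64)
        scalar = arr.ndim == 0
        flat = arr.reshape(-1)
        if flat.size and (flat.min() < 0 or flat.max() > self.n):
            raise RangeError(f"rank position outside [0, {self.n}]")
        out = self._rank_array(flat).reshape(arr.shape)
        return int(out) if scalar else out

    def _rank_array(self, j: np.ndarray) -> np.ndarray:
        out = np.empty(j.shape, dtype=np.int64)
        padded = self.padded_bits
        if padded == 0:
            out[:] = 0
            return out
        at_end = j == padded
        out[at_end] = self.ones_total
        inner = j[~at_end]
        if inner.size == 0:
            return out
        out[~at_end] = self._rank_inner(inner)
        return out

    def _rank_inner(self, j: np.ndarray) -> np.ndarray:
        cfg = self.config
        w1 = cfg.block_bits
        wpw = w1 // WORD_BITS
        bidx, p, ppos, s2 = _query_parts(cfg, j)
        blockwords = self.bits.words.reshape(-1, wpw)[bidx]
        c = _vec_count(blockwords, ppos, w1, cfg.strategy)
        L0 = self.dir.L0
        if cfg.layers == 1:
            base = L0[p].astype(np.int64)
        else:
            w0 = cfg.superblock_bits
            L1 = self.dir.L1.astype(np.int64)
            if cfg.paired:
                q = j // (2 * w0)
                s1 = np.where((j // w0) % 2 == 1, 1, -1)
                base = L0[q].astype(np.int64) + s1 * L1[p]
            else:
                base = L0[j // w0].astype(np.int64) + L1[p]
        return base + s2 * c

    # -- accounting ---------------------------------------------------------

    def storage_bits(self) -> StorageReport:
        """Measured stored-bit breakdown of this structure."""
        return StorageReport(
            structure="bv",
            n=self.n,
            payload_bits=self.bits.words.size * WORD_BITS,
            l1_bits=self.dir.l1_bits,
            l0_bits=self.dir.l0_bits,
            params=_config_params(self.config),
        )

    def with_strategy(self, strategy: str) -> "RankBitVector":
        """Same structure, alternative block-counting strategy."""
        return RankBitVector(self.bits, replace(self.config, strategy=strategy), self.dir, self.ones_total)

    # -- serialization ------------------------------------------------------

    _MAGIC = b"BRNKBV01"
    _HEADER = struct.Struct("<8sBBBxIQQQQQQ")

    def to_bytes(self) -> bytes:
        cfg = self.config
        head = self._HEADER.pack(
            self._MAGIC,
            cfg.layers,
            int(cfg.paired),
            _STRATEGIES.index(cfg.strategy),
            cfg.block_bits,
            cfg.superblock_bits,
            self.n,
            self.ones_total,
            self.bits.words.size,
            self.dir.L0.size,
            0 if self.dir.L1 is None else self.dir.L1.size,
        )
        parts = [head, self.bits.words.astype("<u8").tobytes(), self.dir.L0.astype("<u8").tobytes()]
        if self.dir.L1 is not None:
            parts.append(self.dir.L1.astype("<u2").tobytes())
        return b"".join(parts)

    @classmethod
    def from_bytes(cls, blob: bytes) -> "RankBitVector":
        hs = cls._HEADER.size
        if len(blob) < hs:
            raise FormatError("truncated container")
        (magic, layers, paired, strat, w1, w0, n, ones, nwords, nl0, nl1) = cls._HEADER.unpack_from(blob)
        if magic != cls._MAGIC:
            raise FormatError("not a bitrank bit-vector container")
        if strat >= len(_STRATEGIES):
            raise FormatError("unknown strategy code")
        cfg = RankConfig(block_bits=w1, superblock_bits=w0, paired=bool(paired), layers=layers, strategy=_STRATEGIES[strat])
        off = hs
        end = off + 8 * nwords
        words = np.frombuffer(blob, dtype="<u8", count=nwords, offset=off).astype(_U64)
        off = end
        L0 = np.frombuffer(blob, dtype="<u8", count=nl0, offset=off).astype(_U64)
        off += 8 * nl0
        L1 = None
        if layers == 2:
            L1 = np.frombuffer(blob, dtype="<u2", count=nl1, offset=off).astype(np.uint16)
            off += 2 * nl1
        if off != len(blob):
            raise FormatError("container size mismatch")
        return cls(PackedBits(words, n), cfg, RankDirectory(L0, L1), ones)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            fh.write(self.to_bytes())

    @classmethod
    def load(cls, path) -> "RankBitVector":
        with open(path, "rb") as fh:
            return cls.from_bytes(fh.read())


def _config_params(cfg: RankConfig) -> dict:
    return {
        "block_bits": cfg.block_bits,
        "superblock_bits": cfg.superblock_bits,
        "paired": cfg.paired,
        "layers": cfg.layers,
        "strategy": cfg.strategy,
    }


def build_directory(words: np.ndarray, config: RankConfig) -> RankDirectory:
    """Directory arrays for an already-padded word array."""
    w1 = config.block_bits
    wpw = w1 // WORD_BITS
    nblocks = words.size // wpw
    blockpc = np.bitwise_count(words).reshape(nblocks, wpw).sum(axis=1, dtype=np.int64) if nblocks else np.zeros(0, np.int64)
    # C[j] = number of set bits before block boundary j
    C = np.zeros(nblocks + 1, dtype=np.int64)
    np.cumsum(blockpc, out=C[1:])
    if config.layers == 1:
        if config.paired:
            L0 = C[1 : nblocks + 1 : 2]  # through each pair's left block
        else:
            L0 = C[:nblocks]
        return RankDirectory(L0.astype(_U64))
    w0 = config.superblock_bits
    r = w0 // w1
    nsb = nblocks // r
    if config.paired:
        pairs = nblocks // 2
        pairs_per_sb = r // 2
        p = np.arange(pairs, dtype=np.int64)
        end_left = C[2 * p + 1]  # count through pair p's left block
        s = p // pairs_per_sb  # superblock index of pair p
        in_right = s % 2 == 1
        rel = np.where(in_right, end_left - C[s * r], C[(s + 1) * r] - end_left)
        L0 = C[(2 * np.arange(nsb // 2, dtype=np.int64) + 1) * r]
    else:
        jb = np.arange(nblocks, dtype=np.int64)
        rel = C[jb] - C[(jb // r) * r]
        L0 = C[np.arange(nsb, dtype=np.int64) * r]
    if rel.size:
        assert int(rel.max()) <= w0 - w1 < 1 << L1_ENTRY_BITS
        assert int(rel.min()) >= 0
    return RankDirectory(L0.astype(_U64), rel.astype(np.uint16))


def build(bits, config: RankConfig | None = None) -> RankBitVector:
    """Build a rank-supported bit vector from bits or a :class:`PackedBits`."""
    if config is None:
        config = RankConfig()
    if not isinstance(bits, PackedBits):
        bits = PackedBits.from_bits(bits)
    n = bits.length_bits
    padded = config.padded_bits(n)
    nwords = padded // WORD_BITS
    if bits.padded_bits != padded:
        words = np.zeros(nwords, dtype=_U64)
        words[: min(bits.words.size, nwords)] = bits.words[:nwords]
        bits = PackedBits(words, n)
    directory = build_directory(bits.words, config)
    if config.strategy == "mask":
        make_mask_table(config.block_bits)  # precompute once at construction
    return RankBitVector(bits, config, directory, bits.count())


def rank(v: RankBitVector, i) -> "int | np.ndarray":
    """Module-level alias for :meth:`RankBitVector.rank`."""
    return v.rank(i)


def storage_bits(v: RankBitVector) -> StorageReport:
    """Module-level alias for :meth:`RankBitVector.storage_bits`."""
    return v.storage_bits()


def bv_storage(config: RankConfig, n: int) -> StorageReport:
    """Closed-form accounting for a bit vector of length n (no build needed)."""
    nl1 = config.l1_entries(n)
    nl0 = config.l0_entries(n)
    l0_width = L0_ENTRY_BITS  # single-layer counters are 64-bit as well
    return StorageReport(
        structure="bv",
        n=n,
        payload_bits=config.padded_bits(n),
        l1_bits=L1_ENTRY_BITS * nl1,
        l0_bits=l0_width * nl0,
        params=_config_params(config),
    )
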