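"""Word-level bit storage and the two block-counting strategies.

Bits live in 64-bit words with little-endian bit order: bit ``j`` of word
``t`` holds position ``64*t + j``.  Blocks are groups of 64 or 512 bits
(1 or 8 words).  A rank query needs the popcount of either a prefix or a
suffix of one block; two interchangeable strategies provide it:

* shift-and-count — shift the unwanted bits out, then popcount;
* mask-and-count  — AND with one of ``2w+1`` precomputed masks indexed by
  the query offset within a *pair* of blocks, then popcount.

Offsets in ``[0, w)`` select a suffix of the pair's left block (the bits
to subtract); offsets in ``[w, 2w]`` select a prefix of length
``offset - w`` of the right block (the bits to add).  ``offset == w``
contributes zero bits and is treated as an empty right-block prefix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, RangeError

WORD_BITS = 64
SUPPORTED_BLOCK_BITS = (64, 512)

_U64 = np.uint64
_ONES64 = np.uint64(0xFFFFFFFFFFFFFFFF)


def _ceil_div(a: int, b: int) -> int:
    return -(-a // b)


class PackedBits:
    """A bit string stored as little-endian 64-bit word groups.

    ``length_bits`` is the logical length; the word array may extend
    beyond it (structure padding), in which case every bit at position
    >= ``length_bits`` is zero.
    """

    __slots__ = ("length_bits", "words")

    def __init__(self, words: np.ndarray, length_bits: int):
        words = np.ascontiguousarray(words, dtype=_U64)
        length_bits = int(length_bits)
        if length_bits < 0:
            raise ValueError("negative length")
        if words.size * WORD_BITS < length_bits:
            raise ValueError("word array too short for length_bits")
        self.words = words
        self.length_bits = length_bits

    @classmethod
    def from_bits(cls, bits, padded_length: int | None = None) -> "PackedBits":
        """Pack an iterable of 0/1 values; optionally zero-pad to a longer span."""
        bits = np.asarray(bits, dtype=np.uint8)
        if bits.ndim != 1:
            raise ValueError("expected a 1-d bit array")
        n = bits.size
        if padded_length is None:
            padded_length = n
        if padded_length < n:
            raise ValueError("padded_length shorter than the bit array")
        nwords = _ceil_div(padded_length, WORD_BITS)
        buf = np.zeros(nwords * 8, dtype=np.uint8)
        packed = np.packbits(bits, bitorder="little")
        buf[: packed.size] = packed
        return cls(buf.view("<u8").astype(_U64, copy=False), n)

    @classmethod
    def zeros(cls, length_bits: int, padded_length: int | None = None) -> "PackedBits":
        if padded_length is None:
            padded_length = length_bits
        nwords = _ceil_div(padded_length, WORD_BITS)
        return cls(np.zeros(nwords, dtype=_U64), length_bits)

    @property
    def padded_bits(self) -> int:
        return self.words.size * WORD_BITS

    def __len__(self) -> int:
        return self.length_bits

    def get(self, j: int) -> int:
        if not 0 <= j < self.length_bits:
            raise RangeError(f"bit position {j} outside [0, {self.length_bits})")
        return int(self.words[j >> 6] >> _U64(j & 63)) & 1

    def to_bits(self) -> np.ndarray:
        """Unpack to a uint8 array of length ``length_bits``."""
        raw = self.words.astype("<u8").view(np.uint8)
        return np.unpackbits(raw, bitorder="little")[: self.length_bits]

    def count(self) -> int:
        """Total number of set bits."""
        return int(np.bitwise_count(self.words).sum())


class WordBlock:
    """A view of one block: ``width_bits / 64`` consecutive words."""

    __slots__ = ("width_bits", "words")

    def __init__(self, words, width_bits: int | None = None):
        words = np.ascontiguousarray(words, dtype=_U64)
        if width_bits is None:
            width_bits = words.size * WORD_BITS
        if width_bits % WORD_BITS or words.size * WORD_BITS != width_bits:
            raise ConfigError("block width must cover whole 64-bit words")
        self.words = words
        self.width_bits = int(width_bits)


@dataclass(frozen=True)
class MaskTable:
    """The ``2w+1`` pair-offset masks, each ``w`` bits (``w/64`` words)."""

    width_bits: int
    masks: np.ndarray  # shape (2w+1, w//64), uint64


_TABLE_CACHE: dict[int, MaskTable] = {}


def make_mask_table(width_bits: int) -> MaskTable:
    """Build (once per width) the mask array indexed by pair offset.

    Entry ``j < w`` keeps bits ``j .. w-1`` (left-block suffix); entry
    ``j >= w`` keeps bits ``0 .. j-w-1`` (right-block prefix).  Entry ``w``
    is all-zero; entries ``0`` and ``2w`` are all-ones.
    """
    if width_bits not in SUPPORTED_BLOCK_BITS:
        raise ConfigError(f"unsupported block width {width_bits}; expected one of {SUPPORTED_BLOCK_BITS}")
    cached = _TABLE_CACHE.get(width_bits)
    if cached is not None:
        return cached
    w = width_bits
    wpw = w // WORD_BITS
    masks = np.zeros((2 * w + 1, wpw), dtype=_U64)
    bits = np.zeros(w, dtype=np.uint8)
    for j in range(2 * w + 1):
        bits[:] = 0
        if j < w:
            bits[j:] = 1
        else:
            bits[: j - w] = 1
        masks[j] = np.packbits(bits, bitorder="little").view("<u8")
    masks.setflags(write=False)
    table = MaskTable(w, masks)
    _TABLE_CACHE[width_bits] = table
    return table


def popcount_block(block: WordBlock) -> int:
    """Sum of per-word popcounts over the block."""
    return sum(int(wd).bit_count() for wd in block.words)


def masked_count(block: WordBlock, table: MaskTable, pair_pos: int) -> int:
    """popcount(block AND mask[pair_pos]).

    For ``pair_pos < w`` this is the suffix count of the left block from
    ``pair_pos`` on; for ``pair_pos >= w`` the prefix count of the first
    ``pair_pos - w`` bits of the right block.
    """
    w = table.width_bits
    if block.width_bits != w:
        raise ConfigError("block width does not match mask table width")
    if not 0 <= pair_pos <= 2 * w:
        raise RangeError(f"pair offset {pair_pos} outside [0, {2 * w}]")
    return int(np.bitwise_count(block.words & table.masks[pair_pos]).sum())


def shifted_count(block: WordBlock, pair_pos: int, side: str | None = None) -> int:
    """Same contract as :func:`masked_count`, via word-level shifts.

    Whole words inside the wanted range are popcounted directly; the one
    straddling word has the unwanted bits shifted out first.  ``side`` may
    force the interpretation at the ``pair_pos == w`` boundary (both sides
    contribute zero bits there).
    """
    w = block.width_bits
    if not 0 <= pair_pos <= 2 * w:
        raise RangeError(f"pair offset {pair_pos} outside [0, {2 * w}]")
    if side is None:
        side = "left" if pair_pos < w else "right"
    if side not in ("left", "right"):
        raise ConfigError(f"unknown side {side!r}")
    if side == "left" and pair_pos > w:
        raise RangeError("left-block offsets lie in [0, w]")
    if side == "right" and pair_pos < w:
        raise RangeError("right-block offsets lie in [w, 2w]")
    words = [int(x) for x in block.words]
    if side == "left":
        # suffix starting at pair_pos
        start = pair_pos
        k, r = start // WORD_BITS, start % WORD_BITS
        total = sum(x.bit_count() for x in words[k + 1 :])
        if k < len(words):
            total += (words[k] >> r).bit_count()
        return total
    # right: prefix of length pair_pos - w
    length = pair_pos - w
    k, r = length // WORD_BITS, length % WORD_BITS
    total = sum(x.bit_count() for x in words[:k])
    if r:
        total += ((words[k] << (WORD_BITS - r)) & 0xFFFFFFFFFFFFFFFF).bit_count()
    return total


# ---------------------------------------------------------------------------
# Vectorized kernels used by the rank structures.  ``blockwords`` has shape
# (m, w/64): the words of the block each of m queries falls in.  ``ppos``
# holds pair offsets in [0, 2w].
# ---------------------------------------------------------------------------


def _vec_count_mask(blockwords: np.ndarray, ppos: np.ndarray, table: MaskTable) -> np.ndarray:
    return np.bitwise_count(blockwords & table.masks[ppos]).sum(axis=1, dtype=np.int64)


def _vec_count_shift(blockwords: np.ndarray, ppos: np.ndarray, width_bits: int) -> np.ndarray:
    w = width_bits
    wpw = w // WORD_BITS
    is_right = (ppos >= w)[:, None]
    # p: prefix length (right side) or suffix start (left side)
    p = np.where(ppos >= w, ppos - w, ppos).astype(np.int64)[:, None]
    k = p >> 6
    r = (p & 63).astype(_U64)
    t = np.arange(wpw, dtype=np.int64)[None, :]
    full = np.where(is_right, t < k, t > k)
    at_k = t == k
    # shift amounts stay in [0, 63]; the r == 0 right-side case is zeroed below
    left_shift = (_U64(WORD_BITS) - r) % _U64(WORD_BITS)
    shifted_right = np.where(r > 0, blockwords << left_shift, _U64(0))
    shifted = np.where(is_right, shifted_right, blockwords >> r)
    counts = np.bitwise_count(blockwords).astype(np.int64)
    partial = np.bitwise_count(shifted).astype(np.int64)
    return (counts * full).sum(axis=1) + (partial * at_k).sum(axis=1)


def _vec_count(blockwords: np.ndarray, ppos: np.ndarray, width_bits: int, strategy: str) -> np.ndarray:
    if strategy == "mask":
        return _vec_count_mask(blockwords, ppos, make_mask_table(width_bits))
    if strategy == "shift":
        return _vec_count_shift(blockwords, ppos, width_bits)
    raise ConfigError(f"unknown strategy {strategy!r}")
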