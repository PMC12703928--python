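"""Rank on strings over a fixed alphabet.

Three interchangeable structures:

* ``mbv``  — one full indicator bit vector (with rank directory) per symbol;
* ``fbv``  — the text stored as ``k = ceil(log2 sigma)`` bit planes, plane t
  holding bit t of every symbol code, plus one two-layer rank directory per
  symbol built over its (virtual) indicator vector; indicator words are
  reconstructed on the fly by ANDing planes or their complements;
* ``pfbv`` — fbv with paired-block directories.

Plane complements would turn zero padding into phantom symbol occurrences
(for any code with a 0 bit), so every reconstructed word is ANDed with a
per-word validity mask derived from the text length.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .core_bits import WORD_BITS, PackedBits, _ceil_div, _vec_count
from .errors import AlphabetError, ConfigError, FormatError, RangeError
from .rank_bv import (
    RankConfig,
    RankDirectory,
    _config_params,
    _query_parts,
    build as build_bv,
    build_directory,
    bv_storage,
    RankBitVector,
)
from .report import StorageReport

_U64 = np.uint64
_ONES64 = np.uint64(0xFFFFFFFFFFFFFFFF)

KINDS = ("mbv", "fbv", "pfbv")


@dataclass(frozen=True)
class Alphabet:
    """Mapping between external symbols and internal codes in [0, sigma)."""

    sigma: int
    symbols: Optional[tuple] = None  # external symbol per code, if any

    def __post_init__(self):
        if not 2 <= self.sigma <= 256:
            raise AlphabetError(f"alphabet size {self.sigma} outside [2, 256]")
        if self.symbols is not None and len(self.symbols) != self.sigma:
            raise AlphabetError("symbol list length must equal sigma")

    @property
    def code_bits(self) -> int:
        return max(1, (self.sigma - 1).bit_length())

    @classmethod
    def dna(cls) -> "Alphabet":
        # canonical 2-bit DNA codes: A=00, C=01, G=10, T=11
        return cls(4, ("A", "C", "G", "T"))

    @classmethod
    def integer(cls, sigma: int) -> "Alphabet":
        return cls(sigma)

    @classmethod
    def from_symbols(cls, symbols: Iterable) -> "Alphabet":
        syms = tuple(symbols)
        if len(set(syms)) != len(syms):
            raise AlphabetError("duplicate symbols")
        return cls(len(syms), syms)

    def encode(self, text: Sequence) -> np.ndarray:
        if isinstance(text, np.ndarray) and np.issubdtype(text.dtype, np.integer):
            # already internal codes; validate only
            codes = text.astype(np.int64)
            if codes.size and (codes.min() < 0 or codes.max() >= self.sigma):
                raise AlphabetError(f"code outside [0, {self.sigma})")
            return codes.astype(np.uint8)
        if self.symbols is None:
            codes = np.asarray(list(text) if isinstance(text, (str, bytes)) else text, dtype=np.int64)
            if codes.size and (codes.min() < 0 or codes.max() >= self.sigma):
                raise AlphabetError(f"code outside [0, {self.sigma})")
            return codes.astype(np.uint8)
        lut = {s: i for i, s in enumerate(self.symbols)}
        codes = np.empty(len(text), dtype=np.uint8)
        for j, ch in enumerate(text):
            try:
                codes[j] = lut[ch]
            except KeyError:
                raise AlphabetError(f"symbol {ch!r} not in alphabet") from None
        return codes

    def decode(self, codes: np.ndarray):
        if self.symbols is None:
            return np.asarray(codes)
        return [self.symbols[int(c)] for c in codes]


class FlattenedText:
    """``k`` zero-padded bit planes scattering the code bits of a text."""

    __slots__ = ("length", "alphabet", "planes")

    def __init__(self, length: int, alphabet: Alphabet, planes: list[PackedBits]):
        self.length = int(length)
        self.alphabet = alphabet
        self.planes = planes

    @property
    def code_bits(self) -> int:
        return len(self.planes)

    @property
    def padded_bits(self) -> int:
        return self.planes[0].padded_bits if self.planes else 0


def encode_text(codes, alphabet: Alphabet, config: RankConfig) -> FlattenedText:
    """Scatter each symbol's code bits over ``k`` planes, padded to the
    superblock(-pair) span of ``config``."""
    codes = np.asarray(codes, dtype=np.int64)
    if codes.size and (codes.min() < 0 or codes.max() >= alphabet.sigma):
        raise AlphabetError(f"code outside [0, {alphabet.sigma})")
    n = codes.size
    padded = config.padded_bits(n)
    planes = [
        PackedBits.from_bits(((codes >> t) & 1).astype(np.uint8), padded)
        for t in range(alphabet.code_bits)
    ]
    return FlattenedText(n, alphabet, planes)


def _validity_words(n: int, nwords: int) -> np.ndarray:
    """mask[t] has 1s exactly at the text positions covered by word t."""
    v = np.zeros(nwords, dtype=_U64)
    full = min(n // WORD_BITS, nwords)
    v[:full] = _ONES64
    if full < nwords and n % WORD_BITS:
        v[full] = (_U64(1) << _U64(n % WORD_BITS)) - _U64(1)
    return v


def reconstruct_word(text: FlattenedText, c: int, word_index: int) -> int:
    """64-bit indicator word: bit j set iff the symbol at 64*word_index+j is c.

    Planes whose bit of ``c`` is 0 enter complemented; positions beyond the
    text length are re-zeroed so padding never contributes.
    """
    if not 0 <= c < text.alphabet.sigma:
        raise AlphabetError(f"code {c} outside [0, {text.alphabet.sigma})")
    nwords = text.padded_bits // WORD_BITS
    if not 0 <= word_index < max(nwords, 1):
        raise RangeError(f"word index {word_index} outside padded span")
    acc = 0xFFFFFFFFFFFFFFFF
    for t, plane in enumerate(text.planes):
        wt = int(plane.words[word_index])
        acc &= wt if (c >> t) & 1 else ~wt & 0xFFFFFFFFFFFFFFFF
    lo = word_index * WORD_BITS
    if lo + WORD_BITS <= text.length:
        return acc
    if lo >= text.length:
        return 0
    return acc & ((1 << (text.length - lo)) - 1)


class StringRank:
    """A string with per-symbol rank support (mbv / fbv / pfbv)."""

    __slots__ = ("kind", "alphabet", "config", "n", "_vectors", "_planes", "_valid", "_L0", "_L1", "_ones")

    def __init__(self, kind, alphabet, config, n, vectors=None, planes=None, valid=None, L0=None, L1=None, ones=None):
        self.kind = kind
        self.alphabet = alphabet
        self.config = config
        self.n = int(n)
        self._vectors = vectors
        self._planes = planes
        self._valid = valid
        self._L0 = L0
        self._L1 = L1
        self._ones = ones

    # -- construction -------------------------------------------------------

    @classmethod
    def build(cls, text, alphabet: Alphabet | None = None, kind: str = "fbv",
              config: RankConfig | None = None) -> "StringRank":
        if kind not in KINDS:
            raise ConfigError(f"kind must be one of {KINDS}")
        if alphabet is None:
            alphabet = Alphabet.dna() if isinstance(text, str) else Alphabet.integer(int(np.max(text)) + 1 if len(text) else 2)
        codes = alphabet.encode(text)
        if config is None:
            config = RankConfig(paired=(kind == "pfbv"))
        if config.layers != 2:
            raise ConfigError("string structures use two-layer directories")
        if kind == "fbv" and config.paired:
            raise ConfigError("fbv uses the non-paired directory layout")
        if kind == "pfbv" and not config.paired:
            raise ConfigError("pfbv uses the paired directory layout")
        n = codes.size
        sigma = alphabet.sigma
        if kind == "mbv":
            vectors = [build_bv((codes == c).astype(np.uint8), config) for c in range(sigma)]
            return cls(kind, alphabet, config, n, vectors=vectors)
        text_planes = encode_text(codes, alphabet, config)
        nwords = text_planes.padded_bits // WORD_BITS
        planes = np.stack([p.words for p in text_planes.planes]) if text_planes.planes else np.zeros((alphabet.code_bits, 0), _U64)
        valid = _validity_words(n, nwords)
        padded = config.padded_bits(n)
        L0s, L1s = [], []
        for c in range(sigma):
            ind = PackedBits.from_bits((codes == c).astype(np.uint8), padded)
            d = build_directory(ind.words, config)
            L0s.append(d.L0)
            L1s.append(d.L1)
        L0 = np.stack(L0s) if sigma else None
        L1 = np.stack(L1s)
        ones = np.bincount(codes, minlength=sigma).astype(np.int64)
        return cls(kind, alphabet, config, n, planes=planes, valid=valid, L0=L0, L1=L1, ones=ones)

    @property
    def sigma(self) -> int:
        return self.alphabet.sigma

    @property
    def padded_bits(self) -> int:
        if self.kind == "mbv":
            return self._vectors[0].padded_bits
        return self._planes.shape[1] * WORD_BITS

    def __len__(self) -> int:
        return self.n

    # -- queries ------------------------------------------------------------

    def rank(self, i, c: int) -> "int | np.ndarray":
        """Occurrences of code ``c`` among the first ``i`` symbols."""
        if not 0 <= c < self.sigma:
            raise AlphabetError(f"code {c} outside [0, {self.sigma})")
        if self.kind == "mbv":
            return self._vectors[c].rank(i)
        arr = np.asarray(i, dtype=np.int64)
        scalar = arr.ndim == 0
        flat = arr.reshape(-1)
        if flat.size and (flat.min() < 0 or flat.max() > self.n):
            raise RangeError(f"rank position outside [0, {self.n}]")
        out = self._rank_flat(flat, c).reshape(arr.shape)
        return int(out) if scalar else out

    def _rank_flat(self, j: np.ndarray, c: int) -> np.ndarray:
        out = np.empty(j.shape, dtype=np.int64)
        padded = self.padded_bits
        if padded == 0:
            out[:] = 0
            return out
        at_end = j == padded
        out[at_end] = int(self._ones[c])
        inner = j[~at_end]
        if inner.size:
            out[~at_end] = self._rank_inner(inner, c)
        return out

    def _rank_inner(self, j: np.ndarray, c: int) -> np.ndarray:
        cfg = self.config
        w1 = cfg.block_bits
        w0 = cfg.superblock_bits
        wpw = w1 // WORD_BITS
        bidx, p, ppos, s2 = _query_parts(cfg, j)
        word_idx = bidx[:, None] * wpw + np.arange(wpw, dtype=np.int64)[None, :]
        acc = self._valid[word_idx].copy()
        for t in range(self._planes.shape[0]):
            pw = self._planes[t][word_idx]
            acc &= pw if (c >> t) & 1 else ~pw
        cnt = _vec_count(acc, ppos, w1, cfg.strategy)
        L0c = self._L0[c]
        L1c = self._L1[c].astype(np.int64)
        if cfg.paired:
            q = j // (2 * w0)
            s1 = np.where((j // w0) % 2 == 1, 1, -1)
            base = L0c[q].astype(np.int64) + s1 * L1c[p]
        else:
            base = L0c[j // w0].astype(np.int64) + L1c[p]
        return base + s2 * cnt

    def access(self, i: int) -> int:
        """Symbol code at position ``i``, reassembled from the stored layers."""
        if not 0 <= i < self.n:
            raise RangeError(f"position {i} outside [0, {self.n})")
        if self.kind == "mbv":
            for c, v in enumerate(self._vectors):
                if v.bits.get(i):
                    return c
            raise AssertionError("position matches no indicator vector")
        widx, r = divmod(i, WORD_BITS)
        code = 0
        for t in range(self._planes.shape[0]):
            code |= (int(self._planes[t][widx]) >> r & 1) << t
        return code

    def with_strategy(self, strategy: str) -> "StringRank":
        from dataclasses import replace

        cfg = replace(self.config, strategy=strategy)
        return StringRank(self.kind, self.alphabet, cfg, self.n, vectors=None if self._vectors is None else [v.with_strategy(strategy) for v in self._vectors], planes=self._planes, valid=self._valid, L0=self._L0, L1=self._L1, ones=self._ones)

    # -- accounting ---------------------------------------------------------

    def storage_bits(self) -> StorageReport:
        """Measured stored-bit breakdown of this structure."""
        if self.kind == "mbv":
            return StorageReport(
                structure=self.kind,
                n=self.n,
                payload_bits=sum(v.bits.words.size * WORD_BITS for v in self._vectors),
                l1_bits=sum(v.dir.l1_bits for v in self._vectors),
                l0_bits=sum(v.dir.l0_bits for v in self._vectors),
                params=dict(_config_params(self.config), sigma=self.sigma),
            )
        return StorageReport(
            structure=self.kind,
            n=self.n,
            payload_bits=self._planes.size * WORD_BITS,
            l1_bits=16 * self._L1.size,
            l0_bits=64 * self._L0.size,
            params=dict(_config_params(self.config), sigma=self.sigma),
        )

    # -- serialization ------------------------------------------------------

    _MAGIC = b"BRNKST01"
    _HEADER = struct.Struct("<8sBBBBIQQHB")

    def to_bytes(self) -> bytes:
        cfg = self.config
        from .rank_bv import _STRATEGIES

        has_syms = self.alphabet.symbols is not None
        head = self._HEADER.pack(
            self._MAGIC,
            KINDS.index(self.kind),
            cfg.layers,
            int(cfg.paired),
            _STRATEGIES.index(cfg.strategy),
            cfg.block_bits,
            cfg.superblock_bits,
            self.n,
            self.sigma,
            int(has_syms),
        )
        parts = [head]
        if has_syms:
            parts.append(bytes(ord(s) if isinstance(s, str) else int(s) for s in self.alphabet.symbols))
        if self.kind == "mbv":
            for v in self._vectors:
                blob = v.to_bytes()
                parts.append(struct.pack("<Q", len(blob)))
                parts.append(blob)
        else:
            k, nwords = self._planes.shape
            nl0 = self._L0.shape[1]
            nl1 = self._L1.shape[1]
            parts.append(struct.pack("<QQQQ", k, nwords, nl0, nl1))
            parts.append(self._planes.astype("<u8").tobytes())
            parts.append(self._L0.astype("<u8").tobytes())
            parts.append(self._L1.astype("<u2").tobytes())
            parts.append(self._ones.astype("<u8").tobytes())
        return b"".join(parts)

    @classmethod
    def from_bytes(cls, blob: bytes) -> "StringRank":
        from .rank_bv import _STRATEGIES

        hs = cls._HEADER.size
        if len(blob) < hs:
            raise FormatError("truncated container")
        magic, kind_code, layers, paired, strat, w1, w0, n, sigma, has_syms = cls._HEADER.unpack_from(blob)
        if magic != cls._MAGIC:
            raise FormatError("not a bitrank string container")
        if kind_code >= len(KINDS):
            raise FormatError("unknown structure kind")
        kind = KINDS[kind_code]
        cfg = RankConfig(block_bits=w1, superblock_bits=w0, paired=bool(paired), layers=layers, strategy=_STRATEGIES[strat])
        off = hs
        symbols = None
        if has_syms:
            symbols = tuple(chr(b) for b in blob[off : off + sigma])
            off += sigma
        alphabet = Alphabet(sigma, symbols)
        if kind == "mbv":
            vectors = []
            for _ in range(sigma):
                (ln,) = struct.unpack_from("<Q", blob, off)
                off += 8
                vectors.append(RankBitVector.from_bytes(blob[off : off + ln]))
                off += ln
            if off != len(blob):
                raise FormatError("container size mismatch")
            return cls(kind, alphabet, cfg, n, vectors=vectors)
        k, nwords, nl0, nl1 = struct.unpack_from("<QQQQ", blob, off)
        off += 32
        planes = np.frombuffer(blob, dtype="<u8", count=k * nwords, offset=off).astype(_U64).reshape(k, nwords)
        off += 8 * k * nwords
        L0 = np.frombuffer(blob, dtype="<u8", count=sigma * nl0, offset=off).astype(_U64).reshape(sigma, nl0)
        off += 8 * sigma * nl0
        L1 = np.frombuffer(blob, dtype="<u2", count=sigma * nl1, offset=off).astype(np.uint16).reshape(sigma, nl1)
        off += 2 * sigma * nl1
        ones = np.frombuffer(blob, dtype="<u8", count=sigma, offset=off).astype(np.int64)
        off += 8 * sigma
        if off != len(blob):
            raise FormatError("container size mismatch")
        valid = _validity_words(n, nwords)
        return cls(kind, alphabet, cfg, n, planes=planes, valid=valid, L0=L0, L1=L1, ones=ones)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            fh.write(self.to_bytes())

    @classmethod
    def load(cls, path) -> "StringRank":
        with open(path, "rb") as fh:
            return cls.from_bytes(fh.read())


def rank_string(s: StringRank, i, c: int):
    """Module-level alias for :meth:`StringRank.rank`."""
    return s.rank(i, c)


def access(s: StringRank, i: int) -> int:
    """Module-level alias for :meth:`StringRank.access`."""
    return s.access(i)


def storage_bits_string(kind: str, config: RankConfig, n: int, sigma: int) -> StorageReport:
    """Closed-form accounting for a string structure (no build needed)."""
    if kind not in KINDS:
        raise ConfigError(f"kind must be one of {KINDS}")
    per_symbol = bv_storage(config, n)
    k = max(1, (sigma - 1).bit_length())
    payload_planes = sigma if kind == "mbv" else k
    return StorageReport(
        structure=kind,
        n=n,
        payload_bits=payload_planes * per_symbol.payload_bits,
        l1_bits=sigma * per_symbol.l1_bits,
        l0_bits=sigma * per_symbol.l0_bits,
        params=dict(_config_params(config), sigma=sigma),
    )


# -- readers ----------------------------------------------------------------


def read_fasta(path, unknown: str = "error"):
    """Read a FASTA file into DNA codes (records concatenated).

    ``unknown`` policy for letters outside ACGT (case-insensitive):
    ``"error"`` raises; ``"extra"`` maps them all to a fifth symbol 'N'.
    """
    from Bio import SeqIO

    if unknown not in ("error", "extra"):
        raise ConfigError("unknown-policy must be 'error' or 'extra'")
    chunks = []
    try:
        records = list(SeqIO.parse(path, "fasta"))
    except (ValueError, OSError) as exc:
        if isinstance(exc, OSError):
            raise
        raise FormatError(f"cannot parse FASTA: {exc}") from exc
    for rec in records:
        chunks.append(str(rec.seq).upper())
    seq = "".join(chunks)
    if not seq:
        raise FormatError("empty input")
    lut = np.full(256, -1, dtype=np.int64)
    for code, ch in enumerate("ACGT"):
        lut[ord(ch)] = code
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = lut[raw]
    bad = codes < 0
    if bad.any():
        if unknown == "error":
            ch = chr(int(raw[bad.argmax()]))
            raise AlphabetError(f"symbol {ch!r} is not a DNA base (policy: error)")
        codes = np.where(bad, 4, codes)
        return codes.astype(np.uint8), Alphabet(5, ("A", "C", "G", "T", "N"))
    return codes.astype(np.uint8), Alphabet.dna()


def read_raw_bytes(path, sigma: int | None = None):
    """Read raw bytes as symbols.

    With ``sigma`` given, byte values are the codes and must be < sigma;
    otherwise distinct byte values become the alphabet in sorted order.
    """
    with open(path, "rb") as fh:
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    if data.size == 0:
        raise FormatError("empty input")
    if sigma is not None:
        if int(data.max()) >= sigma:
            raise AlphabetError(f"byte value {int(data.max())} >= sigma={sigma}")
        return data, Alphabet.integer(sigma)
    values = np.unique(data)
    if values.size < 2:
        values = np.append(values, values[-1] + 1 if values[-1] < 255 else values[-1] - 1)
        values.sort()
    lut = np.zeros(256, dtype=np.uint8)
    lut[values] = np.arange(values.size, dtype=np.uint8)
    return lut[data], Alphabet.from_symbols(int(v) for v in values)
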