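"""Exact stored-bit accounting for rank structures.

All sizes are reported in bits actually stored: the (padded) payload layer,
the 16-bit L1 directory entries and the 64-bit L0 directory entries.
Derived figures follow the conventions of the result tables: directory
overhead as a percentage of the payload length (one decimal) and total
bits per character (three decimals), rounded half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal, localcontext

SCHEMA = "bitrank.storage-report/1"


def round_ratio(numerator: int, denominator: int, places: int) -> float:
    """Round numerator/denominator to `places` decimals, half away from zero."""
    if denominator == 0:
        return 0.0
    with localcontext() as ctx:
        ctx.prec = 50
        q = Decimal(numerator) / Decimal(denominator)
        return float(q.quantize(Decimal(1).scaleb(-places), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StorageReport:
    """Component breakdown of one built (or analytically sized) structure.

    ``payload_bits`` counts the stored bit layer(s) including zero padding;
    ``l1_bits``/``l0_bits`` count directory storage.  ``n`` is the logical
    length (bits of the vector, or characters of the text) used for the
    derived per-unit figures.
    """

    structure: str
    n: int
    payload_bits: int
    l1_bits: int
    l0_bits: int
    params: dict = field(default_factory=dict)

    @property
    def directory_bits(self) -> int:
        return self.l1_bits + self.l0_bits

    @property
    def total_bits(self) -> int:
        return self.payload_bits + self.l1_bits + self.l0_bits

    @property
    def overhead_percent(self) -> float:
        """Directory bits as a percentage of n, one decimal."""
        return round_ratio(100 * self.directory_bits, self.n, 1)

    @property
    def bits_per_char(self) -> float:
        """Total stored bits per logical unit, three decimals."""
        return round_ratio(self.total_bits, self.n, 3)

    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA,
            "structure": self.structure,
            "n": self.n,
            "payload_bits": self.payload_bits,
            "l1_bits": self.l1_bits,
            "l0_bits": self.l0_bits,
            "total_bits": self.total_bits,
            "overhead_percent": self.overhead_percent,
            "bits_per_char": self.bits_per_char,
            "params": dict(self.params),
        }
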