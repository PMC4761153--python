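"""McDonald-Kreitman counts, Neutrality Index and the adaptive fraction alpha.

The MK framework contrasts the nonsynonymous/synonymous ratio within a
species (polymorphism, P_n/P_s) with the same ratio between species
(fixed differences, D_n/D_s). Under strict neutrality the two ratios are
equal; segregating deleterious amino-acid variation pushes NI above 1 and
alpha below 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .popgen import StatisticUndefinedError

__all__ = ["MKCounts", "aggregate_mk", "neutrality_index", "alpha_adaptive"]


@dataclass(frozen=True)
class MKCounts:
    """The 2x2 MK table: polymorphic and fixed counts per functional class."""

    P_n: int
    P_s: int
    D_n: int
    D_s: int

    def __post_init__(self) -> None:
        if min(self.P_n, self.P_s, self.D_n, self.D_s) < 0:
            raise ValueError("MK counts must be non-negative")

    def __add__(self, other: "MKCounts") -> "MKCounts":
        return MKCounts(
            self.P_n + other.P_n,
            self.P_s + other.P_s,
            self.D_n + other.D_n,
            self.D_s + other.D_s,
        )


def aggregate_mk(gene_records: Iterable[MKCounts]) -> MKCounts:
    """Element-wise sum over per-gene tables (counts pooled before ratios)."""
    total = MKCounts(0, 0, 0, 0)
    for rec in gene_records:
        total = total + rec
    return total


def neutrality_index(mk: MKCounts) -> float:
    """NI = (P_n / P_s) / (D_n / D_s); requires P_s > 0 and D_n > 0."""
    if mk.P_s == 0 or mk.D_n == 0:
        raise StatisticUndefinedError(
            f"NI undefined for P_s={mk.P_s}, D_n={mk.D_n}"
        )
    return (mk.P_n / mk.P_s) / (mk.D_n / mk.D_s) if mk.D_s else 0.0


def alpha_adaptive(mk: MKCounts) -> float:
    """alpha = 1 - (D_s P_n) / (D_n P_s); equals 1 - NI where both defined."""
    if mk.P_s == 0 or mk.D_n == 0:
        raise StatisticUndefinedError(
            f"alpha undefined for P_s={mk.P_s}, D_n={mk.D_n}"
        )
    return 1.0 - (mk.D_s * mk.P_n) / (mk.D_n * mk.P_s)
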