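"""Core genomic interval types.

All coordinates in this package follow the BED convention: 0-based,
half-open ``[start, end)``. Readers that accept 1-based input convert at
the boundary; nothing downstream re-interprets coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

VALID_STRANDS = ("+", "-", ".")

FEATURE_KINDS = ("gene", "super_enhancer", "ctcf", "sub_tad")


class IntervalError(ValueError):
    """Raised for invalid genomic coordinates."""


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom
        Chromosome / sequence name; must be non-empty.
    start, end
        0-based inclusive start, exclusive end; ``0 <= start < end``.
    strand
        One of ``+``, ``-`` or ``.`` (unstranded, the default).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise IntervalError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise IntervalError(
                f"require 0 <= start < end, got [{self.start}, {self.end}) "
                f"on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise IntervalError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def contains(self, other: "GenomicInterval") -> bool:
        """Full containment: ``other`` lies entirely inside ``self``."""
        return (
            self.chrom == other.chrom
            and other.start >= self.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and other.start < self.end
            and other.end > self.start
        )


@dataclass(frozen=True)
class Feature:
    """A functional element: gene, super-enhancer, CTCF site or sub-TAD."""

    interval: GenomicInterval
    kind: str
    id: str

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise IntervalError(
                f"unknown feature kind {self.kind!r}; expected one of {FEATURE_KINDS}"
            )


@dataclass
class FeatureSet:
    """A collection of features with unique ids."""

    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [f.id for f in self.features]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise IntervalError(f"duplicate feature id {dup!r}")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def of_kind(self, kind: str) -> "FeatureSet":
        return FeatureSet([f for f in self.features if f.kind == kind])

    @property
    def kinds(self) -> set[str]:
        return {f.kind for f in self.features}

    @staticmethod
    def concat(sets: Iterable["FeatureSet"]) -> "FeatureSet":
        out: list[Feature] = []
        for s in sets:
            out.extend(s.features)
        return FeatureSet(out)
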