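"""Strand-aware genomic intervals, 0-based half-open on the forward strand.

All coordinates inside the package follow this single convention.  BED is
native; GFF3 and browser-style ``chrN:a-b`` spans are 1-based inclusive and
are converted on ingest.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace


class CoordinateError(ValueError):
    """Raised when an interval violates 0 <= start < end."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A span on a named sequence of a named assembly.

    Coordinates are 0-based, half-open, always on the forward strand;
    ``strand`` records orientation as metadata.
    """

    assembly: str
    chrom: str
    start: int
    end: int
    strand: str = field(default="+", compare=True)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise CoordinateError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def same_sequence(self, other: "GenomicInterval") -> bool:
        return self.assembly == other.assembly and self.chrom == other.chrom

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.same_sequence(other)
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if not self.same_sequence(other):
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.same_sequence(other)
            and self.start <= other.start
            and other.end <= self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)

    def __str__(self) -> str:
        return f"{self.assembly}.{self.chrom}:{self.start}-{self.end}({self.strand})"


_REGION_RE = re.compile(
    r"^(?P<chrom>[\w.]+):(?P<start>[\d,]+)\s*[-–—]\s*(?P<end>[\d,]+)$"
)


def parse_region(text: str, assembly: str = "") -> GenomicInterval:
    """Parse a browser-style span like ``chr2:39,790,777-39,791,782``.

    The input is 1-based inclusive (UCSC browser convention) and is
    converted to the internal 0-based half-open convention.  Hyphen,
    en-dash and em-dash separators are accepted.
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise CoordinateError(f"cannot parse region {text!r}")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    if start < 1 or end < start:
        raise CoordinateError(f"invalid 1-based span {text!r}")
    return GenomicInterval(assembly, m.group("chrom"), start - 1, end)


def merge_intervals(ivs: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: sorted, overlapping/adjacent ones merged."""
    out: list[GenomicInterval] = []
    for iv in sorted(ivs, key=lambda v: (v.assembly, v.chrom, v.start, v.end)):
        if out and out[-1].same_sequence(iv) and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = replace(out[-1], end=iv.end)
        else:
            out.append(iv)
    return out
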