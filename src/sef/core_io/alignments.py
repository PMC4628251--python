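"""Pairwise and multiple alignments, with MAF reading and writing.

MAF ``s`` lines on the negative strand are normalized to forward-strand
intervals at parse time (the row text stays reverse-complemented exactly as
in the file; ``strand`` records the original orientation).  The parser is
deliberately written by hand so that format violations can be reported with
the offending line number, which the pipeline's ``validate`` command relies
on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from sef.core_io.intervals import GenomicInterval


class MafFormatError(ValueError):
    """Malformed MAF input; message names the offending line number."""


def ungapped_length(text: str) -> int:
    return len(text) - text.count("-")


def _split_src(src: str) -> tuple[str, str]:
    """Split a MAF src field ``assembly.chrom``; bare names double as both."""
    if "." in src:
        asm, chrom = src.split(".", 1)
        return asm, chrom
    return src, src


@dataclass
class AlignedRow:
    """One gapped row of an alignment block."""

    species: str  # assembly label
    interval: GenomicInterval  # forward-strand span of the ungapped bases
    strand: str  # original strand of the row in the source file
    text: str  # gapped sequence as written (revcomp for '-' rows)
    src_size: int = 0  # chromosome length, 0 if unknown

    def __post_init__(self) -> None:
        if ungapped_length(self.text) != self.interval.length:
            raise MafFormatError(
                f"row {self.species}: ungapped text length "
                f"{ungapped_length(self.text)} != interval length "
                f"{self.interval.length}"
            )

    @property
    def src(self) -> str:
        if self.interval.chrom == self.species:
            return self.species
        return f"{self.species}.{self.interval.chrom}"


@dataclass
class AlignmentBlock:
    """A set of rows of equal gapped length."""

    rows: list[AlignedRow]

    def __post_init__(self) -> None:
        lens = {len(r.text) for r in self.rows}
        if len(lens) > 1:
            raise MafFormatError(f"unequal gapped row lengths in block: {lens}")

    @property
    def width(self) -> int:
        return len(self.rows[0].text) if self.rows else 0

    def row_for(self, species: str) -> AlignedRow | None:
        for r in self.rows:
            if r.species == species:
                return r
        return None


@dataclass
class MultipleAlignment:
    """Blocks of aligned rows with a designated reference species."""

    blocks: list[AlignmentBlock]
    reference: str

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.blocks:
            for r in b.rows:
                seen.setdefault(r.species, None)
        return list(seen)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultipleAlignment):
            return NotImplemented
        if self.reference != other.reference or len(self.blocks) != len(other.blocks):
            return False
        for a, b in zip(self.blocks, other.blocks):
            if len(a.rows) != len(b.rows):
                return False
            for ra, rb in zip(a.rows, b.rows):
                if (ra.species, ra.interval, ra.strand, ra.text) != (
                    rb.species,
                    rb.interval,
                    rb.strand,
                    rb.text,
                ):
                    return False
        return True


@dataclass
class PairwiseBlock:
    """One gapped block of a pairwise alignment."""

    query: GenomicInterval
    target: GenomicInterval
    query_text: str
    target_text: str

    def __post_init__(self) -> None:
        if len(self.query_text) != len(self.target_text):
            raise MafFormatError("pairwise block rows have unequal gapped length")
        if ungapped_length(self.query_text) != self.query.length:
            raise MafFormatError("query text length != query interval length")
        if ungapped_length(self.target_text) != self.target.length:
            raise MafFormatError("target text length != target interval length")


@dataclass
class PairwiseAlignment:
    """Ordered, query-sorted, non-overlapping pairwise alignment blocks."""

    blocks: list[PairwiseBlock]
    query_assembly: str = ""
    target_assembly: str = ""

    def __post_init__(self) -> None:
        if self.blocks:
            if not self.query_assembly:
                self.query_assembly = self.blocks[0].query.assembly
            if not self.target_assembly:
                self.target_assembly = self.blocks[0].target.assembly
        self.blocks.sort(key=lambda b: (b.query.chrom, b.query.start))
        prev: PairwiseBlock | None = None
        for b in self.blocks:
            if (
                prev is not None
                and prev.query.same_sequence(b.query)
                and b.query.start < prev.query.end
            ):
                raise MafFormatError(
                    f"pairwise blocks overlap in query coordinates near "
                    f"{b.query}"
                )
            prev = b

    def reversed(self) -> "PairwiseAlignment":
        """Swap query and target roles."""
        return PairwiseAlignment(
            [
                PairwiseBlock(b.target, b.query, b.target_text, b.query_text)
                for b in self.blocks
            ],
            query_assembly=self.target_assembly,
            target_assembly=self.query_assembly,
        )


# ---------------------------------------------------------------------------
# MAF I/O


def parse_maf(path: str | Path, reference: str | None = None) -> MultipleAlignment:
    """Read a MAF file into a :class:`MultipleAlignment`.

    ``reference`` defaults to the species of the first row of the first
    block.  Negative-strand rows are converted to forward-strand intervals
    (start' = srcSize - start - size) with the original strand retained.
    """
    blocks: list[AlignmentBlock] = []
    rows: list[AlignedRow] = []
    in_block = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                if in_block and rows:
                    blocks.append(_close_block(rows, lineno))
                    rows = []
                    in_block = False
                continue
            code = stripped.split(None, 1)[0]
            if code == "a":
                if in_block and rows:
                    blocks.append(_close_block(rows, lineno))
                    rows = []
                in_block = True
            elif code == "s":
                if not in_block:
                    raise MafFormatError(f"line {lineno}: 's' line outside a block")
                rows.append(_parse_s_line(stripped, lineno))
            elif code in ("i", "e", "q"):
                continue  # annotation lines carry no coordinates we keep
            else:
                raise MafFormatError(
                    f"line {lineno}: unexpected line type {code!r}"
                )
    if in_block and rows:
        blocks.append(_close_block(rows, lineno))
    if not blocks:
        raise MafFormatError("MAF file contains no alignment blocks")
    ref = reference if reference is not None else blocks[0].rows[0].species
    return MultipleAlignment(blocks, reference=ref)


def _parse_s_line(line: str, lineno: int) -> AlignedRow:
    parts = line.split()
    if len(parts) != 7:
        raise MafFormatError(f"line {lineno}: 's' line needs 7 fields, got {len(parts)}")
    _, src, start_s, size_s, strand, src_size_s, text = parts
    try:
        start, size, src_size = int(start_s), int(size_s), int(src_size_s)
    except ValueError as exc:
        raise MafFormatError(f"line {lineno}: non-integer coordinate") from exc
    if size <= 0 or start < 0:
        raise MafFormatError(f"line {lineno}: invalid start/size {start}/{size}")
    if strand not in ("+", "-"):
        raise MafFormatError(f"line {lineno}: invalid strand {strand!r}")
    if ungapped_length(text) != size:
        raise MafFormatError(
            f"line {lineno}: text has {ungapped_length(text)} bases, size says {size}"
        )
    asm, chrom = _split_src(src)
    if strand == "-":
        if src_size <= 0:
            raise MafFormatError(f"line {lineno}: '-' strand row needs srcSize")
        fwd_start = src_size - start - size
    else:
        fwd_start = start
    interval = GenomicInterval(asm, chrom, fwd_start, fwd_start + size, strand)
    return AlignedRow(asm, interval, strand, text, src_size=src_size)


def _close_block(rows: list[AlignedRow], lineno: int) -> AlignmentBlock:
    try:
        return AlignmentBlock(list(rows))
    except MafFormatError as exc:
        raise MafFormatError(f"block ending near line {lineno}: {exc}") from exc


def write_maf(aln: MultipleAlignment, path: str | Path) -> None:
    """Write a MAF file; inverse of :func:`parse_maf` at object level."""
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for block in aln.blocks:
            fh.write("\na\n")
            for r in block.rows:
                if r.strand == "-":
                    src_size = r.src_size or r.interval.end
                    start = src_size - r.interval.end
                else:
                    src_size = r.src_size or r.interval.end
                    start = r.interval.start
                fh.write(
                    f"s {r.src} {start} {r.interval.length} {r.strand} "
                    f"{src_size} {r.text}\n"
                )
        fh.write("\n")


def pairwise_from_maf(
    maf: MultipleAlignment, query: str, target: str
) -> PairwiseAlignment:
    """Extract the (query, target) pairwise projection of a MAF.

    Columns where either row is gapped are kept (the mapper skips them);
    blocks lacking either species are dropped.
    """
    pblocks: list[PairwiseBlock] = []
    for b in maf.blocks:
        qr, tr = b.row_for(query), b.row_for(target)
        if qr is None or tr is None:
            continue
        pblocks.append(PairwiseBlock(qr.interval, tr.interval, qr.text, tr.text))
    return PairwiseAlignment(pblocks, query_assembly=query, target_assembly=target)
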