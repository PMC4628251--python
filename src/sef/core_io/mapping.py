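"""Projection of intervals through pairwise alignments."""

from __future__ import annotations

from sef.core_io.alignments import PairwiseAlignment, PairwiseBlock
from sef.core_io.intervals import GenomicInterval

DEFAULT_MIN_MAPPED_FRACTION = 0.5


def _column_pairs(block: PairwiseBlock):
    """Yield (query_pos, target_pos) per alignment column.

    Positions are forward-strand coordinates; a gapped side yields None.
    Negative-strand rows walk their forward coordinates downward.
    """
    q, t = block.query, block.target
    qpos = q.start if q.strand == "+" else q.end - 1
    tpos = t.start if t.strand == "+" else t.end - 1
    qstep = 1 if q.strand == "+" else -1
    tstep = 1 if t.strand == "+" else -1
    for qc, tc in zip(block.query_text, block.target_text):
        cur_q = qpos if qc != "-" else None
        cur_t = tpos if tc != "-" else None
        yield cur_q, cur_t
        if qc != "-":
            qpos += qstep
        if tc != "-":
            tpos += tstep


def map_interval(
    iv: GenomicInterval,
    aln: PairwiseAlignment,
    min_mapped_fraction: float = DEFAULT_MIN_MAPPED_FRACTION,
) -> GenomicInterval | None:
    """Project ``iv`` from the alignment's query onto its target assembly.

    Returns the target span of the alignment columns covering ``iv``,
    excluding columns where the target is gapped.  Returns ``None`` when
    fewer than ``min_mapped_fraction`` of the interval's bases map, or when
    the interval falls outside all blocks.
    """
    if aln.query_assembly and iv.assembly and iv.assembly != aln.query_assembly:
        raise ValueError(
            f"interval assembly {iv.assembly!r} is not the alignment query "
            f"{aln.query_assembly!r}"
        )
    mapped: list[int] = []
    target_chrom = None
    target_strand = "+"
    for block in aln.blocks:
        if block.query.chrom != iv.chrom:
            continue
        if block.query.end <= iv.start or block.query.start >= iv.end:
            continue
        for qpos, tpos in _column_pairs(block):
            if qpos is None or tpos is None:
                continue
            if iv.start <= qpos < iv.end:
                mapped.append(tpos)
                target_chrom = block.target.chrom
                target_strand = block.target.strand
    if not mapped or len(mapped) < min_mapped_fraction * iv.length:
        return None
    return GenomicInterval(
        aln.target_assembly,
        target_chrom,
        min(mapped),
        max(mapped) + 1,
        target_strand,
    )


def mapped_base_pairs(
    iv: GenomicInterval, aln: PairwiseAlignment
) -> list[tuple[int, int]]:
    """All (query_pos, target_pos) pairs covering ``iv``, both ungapped."""
    pairs: list[tuple[int, int]] = []
    for block in aln.blocks:
        if block.query.chrom != iv.chrom:
            continue
        if block.query.end <= iv.start or block.query.start >= iv.end:
            continue
        for qpos, tpos in _column_pairs(block):
            if qpos is None or tpos is None:
                continue
            if iv.start <= qpos < iv.end:
                pairs.append((qpos, tpos))
    return pairs


def aligned_column_matches(
    iv: GenomicInterval, aln: PairwiseAlignment
) -> list[tuple[int, bool]]:
    """Per aligned column covering ``iv``: (query_pos, bases identical).

    Only columns ungapped on both sides contribute; used for identity
    confirmation of exon matches and projections.
    """
    out: list[tuple[int, bool]] = []
    for block in aln.blocks:
        if block.query.chrom != iv.chrom:
            continue
        if block.query.end <= iv.start or block.query.start >= iv.end:
            continue
        for (qpos, tpos), qc, tc in zip(
            _column_pairs(block), block.query_text, block.target_text
        ):
            if qpos is None or tpos is None:
                continue
            if iv.start <= qpos < iv.end:
                out.append((qpos, qc.upper() == tc.upper()))
    out.sort()
    return out
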