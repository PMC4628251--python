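"""Orthologous exons and introns across reference genomes.

Orthologous introns are the unit of synteny for the whole pipeline: an
intron is accepted only when both bracketing exons match orthologous exons
that are adjacent in the *full* annotated exon order of every species, so
an intervening unmatched exon breaks bracketing and the intron is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from sef.core_io.formats import GeneModel
from sef.core_io.intervals import GenomicInterval
from sef.core_io.mapping import aligned_column_matches, map_interval
from sef.core_io.alignments import PairwiseAlignment

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 0.70
DEFAULT_WINDOW = 100


@dataclass
class ProjectionConfig:
    """70 %-identity / 100 bp-window acceptance rule for projected exons."""

    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
    window: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity threshold must be in (0, 1]")
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass
class ExonMatch:
    """A pair of orthologous exons, annotated in both species or projected."""

    gene_a: str
    gene_b: str
    exon_a: GenomicInterval
    exon_b: GenomicInterval
    support: str = "annotated-both"  # or "projected"
    identity: float = 1.0

    def __post_init__(self) -> None:
        if self.support not in ("annotated-both", "projected"):
            raise ValueError(f"unknown support {self.support!r}")


@dataclass
class OrthologousIntronSet:
    """One intron per species, bracketed by adjacent orthologous exons."""

    gene_ids: dict[str, str]
    introns: dict[str, GenomicInterval]
    upstream_exons: dict[str, GenomicInterval] = field(default_factory=dict)
    downstream_exons: dict[str, GenomicInterval] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return list(self.introns)


def _identity(cols: list[tuple[int, bool]]) -> float:
    if not cols:
        return 0.0
    return sum(1 for _, m in cols if m) / len(cols)


def match_exons(
    annot_a: dict[str, GeneModel],
    annot_b: dict[str, GeneModel],
    ortholog_table: pd.DataFrame,
    pairwise_aln: PairwiseAlignment,
    species_a: str | None = None,
    species_b: str | None = None,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> list[ExonMatch]:
    """Match annotated exons of ortholog gene pairs through the alignment.

    A pair is emitted when the alignment-mapped spans overlap reciprocally
    (>= 1 bp both directions) and ungapped identity over the aligned exon
    is >= ``identity_threshold``.  Genes missing from an annotation are
    skipped with a warning.
    """
    sp_a = species_a or pairwise_aln.query_assembly
    sp_b = species_b or pairwise_aln.target_assembly
    rev = pairwise_aln.reversed()
    matches: list[ExonMatch] = []
    for _, row in ortholog_table.iterrows():
        gid_a, gid_b = row.get(sp_a), row.get(sp_b)
        if gid_a not in annot_a or gid_b not in annot_b:
            logger.warning(
                "ortholog pair (%s, %s) missing from annotations; skipped",
                gid_a,
                gid_b,
            )
            continue
        gene_a, gene_b = annot_a[gid_a], annot_b[gid_b]
        for exon_a in gene_a.exons:
            mapped_a = map_interval(exon_a, pairwise_aln)
            if mapped_a is None:
                continue
            for exon_b in gene_b.exons:
                if mapped_a.overlap_length(exon_b) < 1:
                    continue
                mapped_b = map_interval(exon_b, rev)
                if mapped_b is None or mapped_b.overlap_length(exon_a) < 1:
                    continue
                ident = _identity(aligned_column_matches(exon_a, pairwise_aln))
                if ident < identity_threshold:
                    continue
                matches.append(
                    ExonMatch(gid_a, gid_b, exon_a, exon_b, "annotated-both", ident)
                )
    return matches


def project_exon(
    exon: GenomicInterval,
    pairwise_aln: PairwiseAlignment,
    cfg: ProjectionConfig | None = None,
    gene_a: str = "",
    gene_b: str = "",
) -> ExonMatch | None:
    """Infer a missing exon annotation by projection through the alignment.

    Accepted iff some sliding window of ``cfg.window`` aligned bases
    reaches identity >= ``cfg.identity_threshold``; exons shorter than the
    window are scored over all their aligned bases.
    """
    cfg = cfg or ProjectionConfig()
    projected = map_interval(exon, pairwise_aln)
    if projected is None:
        return None
    cols = aligned_column_matches(exon, pairwise_aln)
    if not cols:
        return None
    flags = [m for _, m in cols]
    w = min(cfg.window, len(flags))
    best = 0.0
    running = sum(flags[:w])
    best = running / w
    for i in range(w, len(flags)):
        running += flags[i] - flags[i - w]
        best = max(best, running / w)
    if best < cfg.identity_threshold:
        return None
    return ExonMatch(gene_a, gene_b, exon, projected, "projected", best)


def _exon_position(gene: GeneModel, exon: GenomicInterval) -> int | None:
    for i, e in enumerate(gene.exons_in_gene_order()):
        if e.start == exon.start and e.end == exon.end:
            return i
    return None


def derive_introns(
    matches: dict[str, list[ExonMatch]],
    annotations: dict[str, dict[str, GeneModel]],
    pivot: str,
) -> list[OrthologousIntronSet]:
    """Derive orthologous introns from per-species exon matches.

    ``matches[sp]`` holds matches whose A side lives on the ``pivot``
    species; a set is emitted for every pivot exon pair that is adjacent in
    the full exon order of the pivot *and* of every other species.  Species
    with inconsistent exon order for a candidate pair are logged and the
    set is skipped.
    """
    if pivot not in annotations:
        raise KeyError(f"pivot species {pivot!r} missing from annotations")
    others = [sp for sp in matches if sp != pivot]
    # pivot gene -> exon position -> per-species matched exon
    per_gene: dict[str, dict[int, dict[str, ExonMatch]]] = {}
    for sp in others:
        for m in matches[sp]:
            gene = annotations[pivot].get(m.gene_a)
            if gene is None:
                continue
            pos = _exon_position(gene, m.exon_a)
            if pos is None:
                continue
            slot = per_gene.setdefault(m.gene_a, {}).setdefault(pos, {})
            if sp in slot and slot[sp].exon_b != m.exon_b:
                logger.warning(
                    "ambiguous match for exon %d of %s in %s; dropped",
                    pos,
                    m.gene_a,
                    sp,
                )
                slot[sp] = None  # type: ignore[assignment]
            elif sp not in slot:
                slot[sp] = m

    out: list[OrthologousIntronSet] = []
    for gid_a, by_pos in sorted(per_gene.items()):
        gene_a = annotations[pivot][gid_a]
        ordered_a = gene_a.exons_in_gene_order()
        for pos in range(len(ordered_a) - 1):
            up, down = by_pos.get(pos, {}), by_pos.get(pos + 1, {})
            if any(sp not in up or up[sp] is None for sp in others):
                continue
            if any(sp not in down or down[sp] is None for sp in others):
                continue
            set_ok = True
            introns: dict[str, GenomicInterval] = {}
            ups: dict[str, GenomicInterval] = {}
            downs: dict[str, GenomicInterval] = {}
            gene_ids: dict[str, str] = {pivot: gid_a}
            # pivot's own intron between the adjacent exon pair
            ea, eb = ordered_a[pos], ordered_a[pos + 1]
            piv_intron = _between(ea, eb)
            if piv_intron is None:
                continue
            introns[pivot] = piv_intron
            ups[pivot], downs[pivot] = ea, eb
            for sp in others:
                mu, md = up[sp], down[sp]
                if mu.gene_b != md.gene_b:
                    set_ok = False
                    break
                gene_b = annotations[sp].get(mu.gene_b)
                if gene_b is None:
                    set_ok = False
                    break
                pu = _exon_position(gene_b, mu.exon_b)
                pd_ = _exon_position(gene_b, md.exon_b)
                if pu is None or pd_ is None or pd_ != pu + 1:
                    logger.info(
                        "exon pair (%d, %d) of %s not adjacent in %s; "
                        "intron set skipped",
                        pos,
                        pos + 1,
                        gid_a,
                        sp,
                    )
                    set_ok = False
                    break
                intron = _between(mu.exon_b, md.exon_b)
                if intron is None:
                    set_ok = False
                    break
                introns[sp] = intron
                ups[sp], downs[sp] = mu.exon_b, md.exon_b
                gene_ids[sp] = mu.gene_b
            if set_ok:
                out.append(OrthologousIntronSet(gene_ids, introns, ups, downs))
    return out


def _between(a: GenomicInterval, b: GenomicInterval) -> GenomicInterval | None:
    """Genomic gap strictly between two exons, or None if they touch."""
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    if hi.start <= lo.end:
        return None
    return GenomicInterval(a.assembly, a.chrom, lo.end, hi.start, a.strand)
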