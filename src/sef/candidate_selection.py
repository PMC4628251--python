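"""Syntenic ECR assembly and candidate prioritization.

Groups cross-group-filtered ECRs into their containing orthologous introns,
keeps introns with at least one ECR in every group, applies the
H3K4me1+/H3K4me3- mark filter where mark data exist, and prioritizes by
per-group ECR counts and gene ontology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from sef.conservation.hmm import ConservedRegion
from sef.core_io.formats import BedRecord
from sef.core_io.intervals import GenomicInterval
from sef.orthology import OrthologousIntronSet

logger = logging.getLogger(__name__)

DEFAULT_GO_TERMS = ("developmental process", "anatomical structure development")


@dataclass
class SelectionConfig:
    max_ecrs_per_group: int = 3
    positive_mark: str = "H3K4me1"
    negative_mark: str = "H3K4me3"
    go_terms: tuple[str, ...] = DEFAULT_GO_TERMS

    def __post_init__(self) -> None:
        if self.max_ecrs_per_group < 1:
            raise ValueError("max_ecrs_per_group must be >= 1")


@dataclass
class SyntenicEcrSet:
    """ECRs of every group that fall inside one orthologous intron set."""

    intron_set: OrthologousIntronSet
    ecrs: dict[str, list[ConservedRegion]]  # group label -> ECRs
    marked: dict[str, list[ConservedRegion]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {g: len(v) for g, v in self.ecrs.items()}

    def gene_id(self, species: str) -> str | None:
        return self.intron_set.gene_ids.get(species)


def group_syntenic(
    intron_sets: list[OrthologousIntronSet],
    per_group_ecrs: dict[str, list[ConservedRegion]],
    group_reference: dict[str, str],
) -> list[SyntenicEcrSet]:
    """Assign ECRs to containing orthologous introns; keep full sets.

    ``group_reference`` maps group label -> reference species whose
    coordinates the group's ECRs (and that species' intron in each set)
    live on.  Full containment is required; a set is retained only with
    >= 1 ECR in every group.
    """
    out: list[SyntenicEcrSet] = []
    for iset in intron_sets:
        ecrs: dict[str, list[ConservedRegion]] = {}
        for group, ref in group_reference.items():
            intron = iset.introns.get(ref)
            if intron is None:
                ecrs[group] = []
                continue
            inside = []
            for ecr in per_group_ecrs.get(group, []):
                if intron.contains(ecr.interval):
                    inside.append(ecr.with_flag("intronic"))
                elif intron.overlaps(ecr.interval):
                    logger.warning(
                        "ECR %s spans the boundary of intron %s; excluded",
                        ecr.interval,
                        intron,
                    )
            ecrs[group] = inside
        if all(len(v) >= 1 for v in ecrs.values()):
            out.append(SyntenicEcrSet(iset, ecrs))
    return out


def mark_filter(
    ecrs: list[ConservedRegion],
    positive_peaks: list[BedRecord] | None,
    negative_peaks: list[BedRecord] | None,
) -> tuple[list[ConservedRegion], list[ConservedRegion], list[ConservedRegion]]:
    """Partition ECRs into (marked, unmarked, both_marked) by >= 1 bp overlap.

    marked = overlaps a positive peak and no negative peak; ECRs
    overlapping both mark types are reported separately.  When no positive
    peak data exist (``None``), all ECRs pass through as marked with a
    logged notice.
    """
    if positive_peaks is None:
        logger.info(
            "no positive-mark data supplied; %d ECRs pass unfiltered", len(ecrs)
        )
        return [e.with_flag("marked") for e in ecrs], [], []
    neg = negative_peaks or []
    marked, unmarked, both = [], [], []
    for ecr in ecrs:
        pos_hit = any(ecr.interval.overlap_length(p.interval) >= 1 for p in positive_peaks)
        neg_hit = any(ecr.interval.overlap_length(p.interval) >= 1 for p in neg)
        if pos_hit and not neg_hit:
            marked.append(ecr.with_flag("marked"))
        elif pos_hit and neg_hit:
            both.append(ecr)
        else:
            unmarked.append(ecr)
    return marked, unmarked, both


def apply_marks(
    sets: list[SyntenicEcrSet],
    peaks: dict[str, tuple[list[BedRecord] | None, list[BedRecord] | None]],
) -> None:
    """Record per-group marked ECRs on each set.

    ``peaks[group]`` is (positive, negative) peak lists; groups absent from
    ``peaks`` (no data) pass all their ECRs as marked.
    """
    for s in sets:
        for group, ecrs in s.ecrs.items():
            pos, neg = peaks.get(group, (None, None))
            marked, _, _ = mark_filter(ecrs, pos, neg)
            s.marked[group] = marked


def prioritize(
    sets: list[SyntenicEcrSet],
    gene_go: dict[str, set[str]],
    cfg: SelectionConfig | None = None,
    go_species: str | None = None,
) -> list[SyntenicEcrSet]:
    """Filter by per-group count and GO terms, then rank candidates.

    Keeps sets whose every group has <= ``cfg.max_ecrs_per_group`` ECRs and
    whose gene carries >= 1 configured GO term (genes absent from the table
    count as no-term and are dropped with a notice).  Ranking keys: number
    of groups with >= 1 marked ECR (descending), then number of
    single-ECR groups (descending) to favour univocal correspondence.
    """
    cfg = cfg or SelectionConfig()
    kept: list[SyntenicEcrSet] = []
    for s in sets:
        if any(n > cfg.max_ecrs_per_group for n in s.counts.values()):
            continue
        gene_ids = (
            [s.intron_set.gene_ids.get(go_species)]
            if go_species
            else list(s.intron_set.gene_ids.values())
        )
        terms: set[str] = set()
        known = False
        for gid in gene_ids:
            if gid in gene_go:
                known = True
                terms |= gene_go[gid]
        if not known:
            logger.info(
                "gene(s) %s absent from GO table; set dropped", gene_ids
            )
            continue
        if not terms & set(cfg.go_terms):
            continue
        kept.append(s)

    def rank_key(s: SyntenicEcrSet) -> tuple[int, int]:
        groups_marked = sum(1 for g in s.ecrs if s.marked.get(g))
        univocal = sum(1 for n in s.counts.values() if n == 1)
        return (-groups_marked, -univocal)

    return sorted(kept, key=rank_key)
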