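"""End-to-end driver: from a study bundle to prioritized candidates.

Chains the pipeline stages over the file bundle written by
:func:`sef.synthetic_data.generate_study` (or any bundle with the same
layout): neutral-model fitting on intronic columns, phylo-HMM ECR calling,
overlap resolution, cross-group subtraction, orthologous-intron synteny,
histone-mark filtering and GO prioritization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sef.candidate_selection import (
    SelectionConfig,
    SyntenicEcrSet,
    apply_marks,
    group_syntenic,
    prioritize,
)
from sef.conservation import (
    ConservedRegion,
    ConservedStateModel,
    NeutralModel,
    Phylogeny,
    fit_neutral,
    resolve_overlaps,
    segment_conserved,
)
from sef.conservation.models import encode_bases
from sef.core_io import (
    parse_maf,
    read_bed,
    read_fasta,
    read_gff3,
    read_go_table,
    read_ortholog_table,
)
from sef.group_filter import (
    HomologySearchConfig,
    remove_aligned,
    remove_homologous,
)
from sef.orthology import derive_introns, match_exons
from sef.synthetic_data.config import SimulationConfig
from sef.synthetic_data.study import StudyBundle


@dataclass
class PipelineResult:
    ecrs: dict[str, list[ConservedRegion]] = field(default_factory=dict)
    kept: dict[str, list[ConservedRegion]] = field(default_factory=dict)
    removed: dict[str, list[ConservedRegion]] = field(default_factory=dict)
    neutral_models: dict[str, NeutralModel] = field(default_factory=dict)
    intron_sets: list = field(default_factory=list)
    syntenic_sets: list[SyntenicEcrSet] = field(default_factory=list)
    candidates: list[SyntenicEcrSet] = field(default_factory=list)


def fit_group_neutral(
    bundle: StudyBundle,
    cfg: SimulationConfig,
    group_label: str,
    max_columns: int = 4000,
) -> NeutralModel:
    """Fit a neutral model for one group on putatively neutral (intronic,
    non-exonic) alignment columns of its within-group MAF."""
    group = next(g for g in cfg.groups if g.label == group_label)
    aln = parse_maf(bundle.group_maf[group_label], reference=group.reference)
    topo = Phylogeny.from_newick(group.newick)
    block = aln.blocks[0]
    labels = topo.leaf_labels
    mat = np.full((len(labels), block.width), -1, dtype=np.int8)
    for row in block.rows:
        mat[labels.index(row.species)] = encode_bases(row.text)
    ref_row = block.row_for(group.reference)
    exonic = np.zeros(block.width, dtype=bool)
    genes = read_gff3(bundle.gff3[group.reference], assembly=group.reference)
    exon_mask = np.zeros(ref_row.interval.end, dtype=bool)
    for g in genes.values():
        for e in g.exons:
            exon_mask[e.start : e.end] = True
    pos = ref_row.interval.start
    for i, c in enumerate(ref_row.text):
        if c != "-":
            exonic[i] = exon_mask[pos]
            pos += 1
        else:
            exonic[i] = True  # skip ref-gap columns for fitting
    sel = np.flatnonzero(~exonic)
    if sel.size > max_columns:
        sel = sel[np.linspace(0, sel.size - 1, max_columns).astype(int)]
    return fit_neutral(mat[:, sel], topo, cfg.subst_family)


def call_ecrs(
    bundle: StudyBundle,
    cfg: SimulationConfig,
    csm: ConservedStateModel | None = None,
    min_ecr_length: int = 30,
) -> PipelineResult:
    """Fit neutral models and call overlap-resolved ECRs for every group."""
    csm = csm or ConservedStateModel()
    result = PipelineResult()
    for group in cfg.groups:
        neutral = fit_group_neutral(bundle, cfg, group.label)
        aln = parse_maf(bundle.group_maf[group.label], reference=group.reference)
        ecrs, _ = segment_conserved(
            aln, neutral, csm, min_ecr_length=min_ecr_length, group=group.label
        )
        result.neutral_models[group.label] = neutral
        result.ecrs[group.label] = resolve_overlaps(ecrs)
    return result


def cross_group_filter(
    bundle: StudyBundle,
    cfg: SimulationConfig,
    result: PipelineResult,
    homology_cfg: HomologySearchConfig | None = None,
) -> PipelineResult:
    """Remove ECRs aligned or homologous to any other group's reference."""
    genomes = {
        g.reference: read_fasta(bundle.fasta[g.reference]) for g in cfg.groups
    }
    for group in cfg.groups:
        ref = group.reference
        alns = [
            pw
            for (a, b), pw in bundle.inter_alignments.items()
            if ref in (a, b)
        ]
        kept, removed = remove_aligned(result.ecrs[group.label], alns)
        own = genomes[ref]
        seqs = {
            str(e.interval): own[e.interval.chrom][e.interval.start : e.interval.end]
            for e in kept
        }
        others = [genomes[g.reference] for g in cfg.groups if g.label != group.label]
        kept, removed2 = remove_homologous(kept, seqs, others, homology_cfg)
        result.kept[group.label] = kept
        result.removed[group.label] = removed + removed2
    return result


def assemble_candidates(
    bundle: StudyBundle,
    cfg: SimulationConfig,
    result: PipelineResult,
    selection: SelectionConfig | None = None,
) -> PipelineResult:
    """Orthologous introns -> syntenic sets -> marks -> GO prioritization."""
    refs = [g.reference for g in cfg.groups]
    pivot = refs[0]
    annots = {sp: read_gff3(bundle.gff3[sp], assembly=sp) for sp in refs}
    table = read_ortholog_table(bundle.ortholog_tsv)
    matches = {}
    for sp in refs[1:]:
        key = (pivot, sp) if (pivot, sp) in bundle.inter_alignments else (sp, pivot)
        pw = bundle.inter_alignments[key]
        if pw.query_assembly != pivot:
            pw = pw.reversed()
        matches[sp] = match_exons(annots[pivot], annots[sp], table, pw)
    result.intron_sets = derive_introns(matches, annots, pivot=pivot)
    group_ref = {g.label: g.reference for g in cfg.groups}
    result.syntenic_sets = group_syntenic(result.intron_sets, result.kept, group_ref)
    peaks = {}
    for g in cfg.groups:
        ref = g.reference
        if ref in bundle.me1_bed:
            peaks[g.label] = (
                read_bed(bundle.me1_bed[ref], assembly=ref),
                read_bed(bundle.me3_bed[ref], assembly=ref)
                if ref in bundle.me3_bed
                else [],
            )
    apply_marks(result.syntenic_sets, peaks)
    go = read_go_table(bundle.go_tsv)
    result.candidates = prioritize(result.syntenic_sets, go, selection)
    return result


def run_pipeline(
    bundle: StudyBundle,
    cfg: SimulationConfig,
    csm: ConservedStateModel | None = None,
    min_ecr_length: int = 30,
) -> PipelineResult:
    result = call_ecrs(bundle, cfg, csm, min_ecr_length)
    result = cross_group_filter(bundle, cfg, result)
    return assemble_candidates(bundle, cfg, result)
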