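"""Full synthetic study bundle with planted ground truth.

Lays out orthologous genes on one chromosome per species, evolves each
group from its own root (introns redrawn per group so between-group
conservation is absent by construction), plants within-group conserved
elements, cross-group decoys, exact shared motifs, histone-mark peaks and
reporter-assay count tables, and writes everything as plain-text files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sef.conservation.models import ALPHABET, Phylogeny, SubstitutionModel
from sef.core_io.alignments import (
    AlignedRow,
    AlignmentBlock,
    MultipleAlignment,
    PairwiseAlignment,
    PairwiseBlock,
    write_maf,
)
from sef.core_io.formats import BedRecord, GeneModel, write_bed, write_fasta, write_gff3
from sef.core_io.intervals import GenomicInterval
from sef.synthetic_data.config import SimulationConfig, TruthTable
from sef.synthetic_data.evolve import encode_seq, evolve_on_tree

TISSUES = [
    "epidermis",
    "hindbrain",
    "somitic muscle",
    "otic vesicle",
    "notochord",
    "spinal cord",
]
ACTIVE_RATE = 0.35
BACKGROUND_RATE = 0.02
ECTOPIC_RATE = 0.05
GO_ENHANCER_TERM = "developmental process"
GO_OTHER_TERM = "metabolic process"


@dataclass
class GeneLayout:
    """Shared coordinates of one gene (identical across species)."""

    index: int
    exons: list[tuple[int, int]]
    introns: list[tuple[int, int]]


@dataclass
class StudyBundle:
    """Paths of everything :func:`generate_study` wrote, plus the truth."""

    out_dir: Path
    fasta: dict[str, Path] = field(default_factory=dict)
    gff3: dict[str, Path] = field(default_factory=dict)
    group_maf: dict[str, Path] = field(default_factory=dict)
    inter_maf: dict[tuple[str, str], Path] = field(default_factory=dict)
    me1_bed: dict[str, Path] = field(default_factory=dict)
    me3_bed: dict[str, Path] = field(default_factory=dict)
    ortholog_tsv: Path | None = None
    go_tsv: Path | None = None
    assay_tsv: Path | None = None
    background_tsv: Path | None = None
    truth: TruthTable = field(default_factory=TruthTable)
    group_alignments: dict[str, MultipleAlignment] = field(default_factory=dict)
    inter_alignments: dict[tuple[str, str], PairwiseAlignment] = field(
        default_factory=dict
    )


def build_layout(cfg: SimulationConfig) -> tuple[list[GeneLayout], int]:
    genes: list[GeneLayout] = []
    pos = cfg.spacer_length
    for g in range(cfg.n_genes):
        exons, introns = [], []
        for e in range(cfg.exons_per_gene):
            exons.append((pos, pos + cfg.exon_length))
            pos += cfg.exon_length
            if e < cfg.exons_per_gene - 1:
                introns.append((pos, pos + cfg.intron_length))
                pos += cfg.intron_length
        genes.append(GeneLayout(g, exons, introns))
        pos += cfg.spacer_length
    return genes, pos


def _ecr_span(cfg: SimulationConfig, layout: list[GeneLayout], idx: int) -> tuple[int, int]:
    spec = cfg.planted_ecrs[idx]
    i_start, i_end = layout[spec.gene].introns[spec.intron]
    if spec.offset is not None:
        start = i_start + spec.offset
    else:
        start = i_start + (i_end - i_start - spec.length) // 2
    if start < i_start or start + spec.length > i_end:
        raise ValueError(f"planted ECR {idx} does not fit inside its intron")
    return start, start + spec.length


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def generate_study(cfg: SimulationConfig, out_dir: str | Path) -> StudyBundle:
    """Simulate the full input universe of the pipeline.

    Deterministic: all outputs are a pure function of (config, seed).
    """
    if not cfg.groups:
        raise ValueError("config needs at least one group")
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    for sub in ("fasta", "gff", "maf", "marks", "tables", "truth"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    bundle = StudyBundle(out_dir=out)

    layout, chrom_len = build_layout(cfg)
    master = rng.integers(0, 4, size=chrom_len).astype(np.int8)
    model = SubstitutionModel(cfg.subst_family)

    exon_sites = np.zeros(chrom_len, dtype=bool)
    for gene in layout:
        for s, e in gene.exons:
            exon_sites[s:e] = True
    ecr_spans = [_ecr_span(cfg, layout, i) for i in range(len(cfg.planted_ecrs))]

    # base per-site within-group scaling, before group-specific motif freezes
    base_scales = np.ones(chrom_len)
    base_scales[exon_sites] = cfg.exon_scale
    for (s, e), spec in zip(ecr_spans, cfg.planted_ecrs):
        base_scales[s:e] = spec.scale

    group_leaf_seqs: dict[str, dict[str, str]] = {}
    motif_positions: dict[str, list[tuple[int, int, str]]] = {}  # group -> (motif idx, start, strand)
    for group in cfg.groups:
        tree = Phylogeny.from_newick(group.newick)
        root = master.copy()
        # redraw intron sequence (incl. resample-mode ECRs) per group
        resample = ~exon_sites.copy()
        for (s, e), spec in zip(ecr_spans, cfg.planted_ecrs):
            if spec.mode == "copy":
                resample[s:e] = False
        idx = np.flatnonzero(resample)
        root[idx] = rng.integers(0, 4, size=idx.size)
        # exons diverge slowly between groups but stay alignable
        p = model.transition_matrix(cfg.intergroup_exon_divergence)
        eidx = np.flatnonzero(exon_sites)
        for old in range(4):
            sel = eidx[root[eidx] == old]
            if sel.size:
                root[sel] = rng.choice(4, size=sel.size, p=p[old])
        # plant motifs (group-specific offsets/strands), freeze their sites
        scales = base_scales.copy()
        motif_positions[group.label] = []
        for mi, mspec in enumerate(cfg.planted_motifs):
            es, _ = ecr_spans[mspec.ecr]
            start = es + mspec.offset_for(group.label)
            strand = mspec.strand_for(group.label)
            text = mspec.sequence if strand == "+" else revcomp(mspec.sequence)
            root[start : start + len(text)] = encode_seq(text)
            scales[start : start + len(text)] = 0.0
            motif_positions[group.label].append((mi, start, strand))

        root_seq = "".join(ALPHABET[b] for b in root)
        leaf_seqs, aln = evolve_on_tree(
            root_seq,
            tree,
            model,
            scale=1.0,
            rng=rng,
            site_scales=scales,
            indel_rate=cfg.indel_rate,
        )
        aln.reference = group.reference
        group_leaf_seqs[group.label] = leaf_seqs
        bundle.group_alignments[group.label] = aln
        maf_path = out / "maf" / f"group_{group.label}.maf"
        write_maf(aln, maf_path)
        bundle.group_maf[group.label] = maf_path

    # per-species FASTA and GFF3
    for group in cfg.groups:
        for species, seq in group_leaf_seqs[group.label].items():
            fa = out / "fasta" / f"{species}.fa"
            write_fasta({"chr1": seq}, fa)
            bundle.fasta[species] = fa
            genes = {}
            for gene in layout:
                gid = f"g{gene.index}_{species}"
                g_start, g_end = gene.exons[0][0], gene.exons[-1][1]
                gm = GeneModel(
                    gid, GenomicInterval(species, "chr1", g_start, g_end, "+")
                )
                gm.exons = [
                    GenomicInterval(species, "chr1", s, e, "+")
                    for s, e in gene.exons
                ]
                genes[gid] = gm
            gpath = out / "gff" / f"{species}.gff3"
            write_gff3(genes, gpath)
            bundle.gff3[species] = gpath

    # inter-group pairwise alignments of reference species: exons + decoys
    alignable: list[tuple[int, int]] = [
        (s, e) for gene in layout for (s, e) in gene.exons
    ]
    alignable += [
        span
        for span, spec in zip(ecr_spans, cfg.planted_ecrs)
        if spec.mode == "copy"
    ]
    alignable.sort()
    refs = [(g.label, g.reference) for g in cfg.groups]
    for i in range(len(refs)):
        for j in range(i + 1, len(refs)):
            (gl_a, ref_a), (gl_b, ref_b) = refs[i], refs[j]
            seq_a = group_leaf_seqs[gl_a][ref_a]
            seq_b = group_leaf_seqs[gl_b][ref_b]
            blocks = [
                PairwiseBlock(
                    GenomicInterval(ref_a, "chr1", s, e),
                    GenomicInterval(ref_b, "chr1", s, e),
                    seq_a[s:e],
                    seq_b[s:e],
                )
                for s, e in alignable
            ]
            pw = PairwiseAlignment(blocks, ref_a, ref_b)
            bundle.inter_alignments[(ref_a, ref_b)] = pw
            maf = MultipleAlignment(
                [
                    AlignmentBlock(
                        [
                            AlignedRow(ref_a, b.query, "+", b.query_text, len(seq_a)),
                            AlignedRow(ref_b, b.target, "+", b.target_text, len(seq_b)),
                        ]
                    )
                    for b in pw.blocks
                ],
                reference=ref_a,
            )
            path = out / "maf" / f"inter_{ref_a}_{ref_b}.maf"
            write_maf(maf, path)
            bundle.inter_maf[(ref_a, ref_b)] = path

    _write_truth_and_tables(cfg, layout, ecr_spans, motif_positions, bundle, rng)
    return bundle


def _write_truth_and_tables(
    cfg: SimulationConfig,
    layout: list[GeneLayout],
    ecr_spans: list[tuple[int, int]],
    motif_positions: dict[str, list[tuple[int, int, str]]],
    bundle: StudyBundle,
    rng: np.random.Generator,
) -> None:
    out = bundle.out_dir
    truth = bundle.truth
    all_species = [sp for g in cfg.groups for sp in g.species]
    group_of = {sp: g.label for g in cfg.groups for sp in g.species}

    for i, ((s, e), spec) in enumerate(zip(ecr_spans, cfg.planted_ecrs)):
        target = truth.ecrs if spec.mode == "resample" else truth.decoy_ecrs
        target[i] = {
            sp: GenomicInterval(sp, "chr1", s, e) for sp in all_species
        }
    for g in cfg.groups:
        for mi, start, strand in motif_positions[g.label]:
            width = len(cfg.planted_motifs[mi].sequence)
            for sp in g.species:
                truth.motifs.setdefault(mi, {})[sp] = (
                    GenomicInterval(sp, "chr1", start, start + width),
                    strand,
                )
    for gene in layout:
        for ii, (s, e) in enumerate(gene.introns):
            truth.introns[(gene.index, ii)] = {
                sp: GenomicInterval(sp, "chr1", s, e) for sp in all_species
            }

    # ortholog table over the group reference species
    ref_species = [g.reference for g in cfg.groups]
    rows = [
        {sp: f"g{gene.index}_{sp}" for sp in ref_species} for gene in layout
    ]
    ortho = pd.DataFrame(rows, columns=ref_species)
    bundle.ortholog_tsv = out / "tables" / "orthologs.tsv"
    ortho.to_csv(bundle.ortholog_tsv, sep="\t", index=False)

    # GO table: genes hosting a true planted ECR are developmental
    enhancer_genes = {
        cfg.planted_ecrs[i].gene
        for i in truth.ecrs
    }
    go_rows = []
    for gene in layout:
        term = GO_ENHANCER_TERM if gene.index in enhancer_genes else GO_OTHER_TERM
        for sp in ref_species:
            go_rows.append((f"g{gene.index}_{sp}", term))
    bundle.go_tsv = out / "tables" / "gene2go.tsv"
    pd.DataFrame(go_rows, columns=["gene", "term"]).to_csv(
        bundle.go_tsv, sep="\t", index=False
    )

    # histone marks on the mark-bearing group references
    mark_groups = cfg.mark_spec.groups_with_marks or [g.label for g in cfg.groups]
    true_idx = sorted(truth.ecrs)
    n_me1 = int(round(cfg.mark_spec.me1_fraction * len(true_idx)))
    n_me3 = int(round(cfg.mark_spec.me3_fraction * len(true_idx)))
    pad = cfg.mark_spec.peak_padding
    for g in cfg.groups:
        if g.label not in mark_groups:
            continue
        sp = g.reference
        me1 = [
            BedRecord(
                GenomicInterval(
                    sp,
                    "chr1",
                    max(0, ecr_spans[i][0] - pad),
                    ecr_spans[i][1] + pad,
                ),
                name=f"me1_{i}",
            )
            for i in true_idx[:n_me1]
        ]
        me3 = [
            BedRecord(
                GenomicInterval(
                    sp,
                    "chr1",
                    max(0, ecr_spans[i][0] - pad),
                    ecr_spans[i][1] + pad,
                ),
                name=f"me3_{i}",
            )
            for i in true_idx[:n_me3]
        ]
        p1 = out / "marks" / f"{sp}_h3k4me1.bed"
        p3 = out / "marks" / f"{sp}_h3k4me3.bed"
        write_bed(me1, p1)
        write_bed(me3, p3)
        bundle.me1_bed[sp] = p1
        bundle.me3_bed[sp] = p3

    # reporter assay counts for constructs from the first two groups
    assay_rows, bg_rows = [], []
    times = (24, 48)
    for tissue in TISSUES:
        for t in times:
            bg_rows.append(
                {
                    "construct": "empty_vector",
                    "time_hpf": t,
                    "tissue": tissue,
                    "n_expressing": int(rng.binomial(100, BACKGROUND_RATE)),
                    "n_ectopic": 0,
                    "n_alive": 100,
                }
            )
    assay_groups = cfg.groups[: min(2, len(cfg.groups))]
    for i in sorted(truth.ecrs):
        k = int(rng.integers(1, 3))
        active = list(rng.choice(TISSUES, size=k, replace=False))
        for g in assay_groups:
            cid = f"ecr{i}_{g.label}"
            activity: dict[tuple[str, int], float] = {}
            for tissue in TISSUES:
                for t in times:
                    rate = ACTIVE_RATE if tissue in active else BACKGROUND_RATE
                    activity[(tissue, t)] = rate
                    n_alive = int(rng.integers(90, 121))
                    n_expr = int(rng.binomial(n_alive, rate))
                    n_ect = int(rng.binomial(n_expr, ECTOPIC_RATE)) if n_expr else 0
                    assay_rows.append(
                        {
                            "construct": cid,
                            "time_hpf": t,
                            "tissue": tissue,
                            "n_expressing": n_expr,
                            "n_ectopic": n_ect,
                            "n_alive": n_alive,
                        }
                    )
            truth.construct_activity[cid] = activity
    bundle.assay_tsv = out / "tables" / "assay_counts.tsv"
    bundle.background_tsv = out / "tables" / "assay_background.tsv"
    pd.DataFrame(assay_rows).to_csv(bundle.assay_tsv, sep="\t", index=False)
    pd.DataFrame(bg_rows).to_csv(bundle.background_tsv, sep="\t", index=False)

    _write_truth_tsvs(truth, out / "truth")


def _write_truth_tsvs(truth: TruthTable, tdir: Path) -> None:
    def iv_rows(d: dict) -> list[dict]:
        rows = []
        for key in sorted(d):
            for sp in sorted(d[key]):
                iv = d[key][sp]
                rows.append(
                    {
                        "id": key if not isinstance(key, tuple) else f"{key[0]}.{key[1]}",
                        "species": sp,
                        "chrom": iv.chrom,
                        "start": iv.start,
                        "end": iv.end,
                    }
                )
        return rows

    pd.DataFrame(iv_rows(truth.ecrs)).to_csv(tdir / "ecrs.tsv", sep="\t", index=False)
    pd.DataFrame(iv_rows(truth.decoy_ecrs)).to_csv(
        tdir / "decoy_ecrs.tsv", sep="\t", index=False
    )
    pd.DataFrame(iv_rows(truth.introns)).to_csv(
        tdir / "introns.tsv", sep="\t", index=False
    )
    motif_rows = []
    for mi in sorted(truth.motifs):
        for sp in sorted(truth.motifs[mi]):
            iv, strand = truth.motifs[mi][sp]
            motif_rows.append(
                {
                    "motif": mi,
                    "species": sp,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "strand": strand,
                }
            )
    pd.DataFrame(motif_rows).to_csv(tdir / "motifs.tsv", sep="\t", index=False)
    act_rows = [
        {
            "construct": cid,
            "tissue": tissue,
            "time_hpf": t,
            "rate": rate,
        }
        for cid, act in sorted(truth.construct_activity.items())
        for (tissue, t), rate in sorted(act.items())
    ]
    pd.DataFrame(act_rows).to_csv(tdir / "activity.tsv", sep="\t", index=False)
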