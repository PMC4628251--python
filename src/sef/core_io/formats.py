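"""Readers and writers for the standard flat formats used by the pipeline.

FASTA goes through Biopython; BED, GFF3 and the TSV tables are simple
columnar formats read with pandas / plain parsing.  The MEME-minimal motif
reader is implemented here because Biopython's ``minimal`` parser
reconstructs integer counts from ``nsites`` and thereby distorts the
published column probabilities.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from sef.core_io.intervals import CoordinateError, GenomicInterval

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences keyed by record id (uppercased off; case preserved)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED


@dataclass
class BedRecord:
    interval: GenomicInterval
    name: str = "."
    score: float = 0.0


def read_bed(path: str | Path, assembly: str = "") -> list[BedRecord]:
    """Read BED3/BED6; coordinates are already 0-based half-open."""
    records: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CoordinateError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise CoordinateError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end or start < 0:
                raise CoordinateError(
                    f"{path}:{lineno}: invalid span {start}-{end}"
                )
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "+"
            records.append(
                BedRecord(GenomicInterval(assembly, chrom, start, end, strand), name, score)
            )
    return records


def write_bed(records: list[BedRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.name}\t{r.score:g}\t{r.interval.strand}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 gene models


@dataclass
class GeneModel:
    """A gene with its ordered exons (by genomic start)."""

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    @property
    def strand(self) -> str:
        return self.interval.strand

    def exons_in_gene_order(self) -> list[GenomicInterval]:
        """Exons ordered 5' to 3' with respect to the gene's strand."""
        ordered = sorted(self.exons, key=lambda e: e.start)
        return ordered if self.strand == "+" else ordered[::-1]

    def introns(self) -> list[GenomicInterval]:
        """Gaps between genomically consecutive exons."""
        ordered = sorted(self.exons, key=lambda e: e.start)
        out = []
        for a, b in zip(ordered, ordered[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(
                        self.interval.assembly,
                        self.interval.chrom,
                        a.end,
                        b.start,
                        self.strand,
                    )
                )
        return out


_ATTR_RE = re.compile(r"(\w+)=([^;]+)")


def read_gff3(path: str | Path, assembly: str = "") -> dict[str, GeneModel]:
    """Read gene and exon features from GFF3 (1-based inclusive on disk).

    Exons are attached to genes via their ``Parent`` attribute (directly or
    through an mRNA feature).
    """
    genes: dict[str, GeneModel] = {}
    transcript_gene: dict[str, str] = {}
    exon_rows: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise CoordinateError(f"{path}:{lineno}: GFF3 needs 9 columns")
            chrom, _, ftype, start_s, end_s, _, strand, _, attrs_s = parts
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise CoordinateError(f"{path}:{lineno}: bad coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise CoordinateError(
                    f"{path}:{lineno}: invalid 1-based span {start1}-{end1}"
                )
            attrs = dict(_ATTR_RE.findall(attrs_s))
            iv = GenomicInterval(assembly, chrom, start1 - 1, end1, strand)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise CoordinateError(f"{path}:{lineno}: gene without ID")
                genes[gid] = GeneModel(gid, iv)
            elif ftype in ("mRNA", "transcript"):
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if tid and parent:
                    transcript_gene[tid] = parent
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise CoordinateError(f"{path}:{lineno}: exon without Parent")
                exon_rows.append((parent, iv))
    for parent, iv in exon_rows:
        gid = transcript_gene.get(parent, parent)
        if gid in genes:
            genes[gid].exons.append(iv)
    for g in genes.values():
        g.exons.sort(key=lambda e: e.start)
    return genes


def write_gff3(genes: dict[str, GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.values():
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tsef\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id}\n"
            )
            for i, e in enumerate(sorted(g.exons, key=lambda x: x.start), 1):
                fh.write(
                    f"{e.chrom}\tsef\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\tID={g.gene_id}.e{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# TSV tables


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    """Homologene-like table: one column per species, one row per ortholog group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("ortholog table needs >= 2 species columns")
    return df


def read_go_table(path: str | Path) -> dict[str, set[str]]:
    """gene_id -> set of GO term labels."""
    df = pd.read_csv(path, sep="\t", dtype=str, names=["gene", "term"], header=0)
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        out.setdefault(gene, set()).add(term)
    return out


def read_assay_table(path: str | Path) -> pd.DataFrame:
    """Reporter-assay count table.

    Columns: construct, time_hpf, tissue, n_expressing, n_ectopic, n_alive.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"construct", "time_hpf", "tissue", "n_expressing", "n_ectopic", "n_alive"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    bad = df[(df.n_expressing > df.n_alive) | (df.n_ectopic > df.n_expressing)]
    if len(bad):
        raise ValueError(f"assay table has inconsistent counts in {len(bad)} rows")
    return df


# ---------------------------------------------------------------------------
# MEME minimal motif format


@dataclass
class Pfm:
    """Position frequency matrix; ``matrix`` is 4 x width, rows A,C,G,T."""

    motif_id: str
    tf_name: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError(f"PFM {self.motif_id}: matrix must be 4 x width")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"PFM {self.motif_id}: columns must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))


def read_meme_minimal(path: str | Path) -> list[Pfm]:
    pfms: list[Pfm] = []
    name = tf = None
    rows: list[list[float]] = []
    expect = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                if name is not None and rows:
                    pfms.append(Pfm(name, tf or name, np.array(rows).T))
                parts = line.split()
                name = parts[1] if len(parts) > 1 else "?"
                tf = parts[2] if len(parts) > 2 else name
                rows, expect = [], 0
            elif line.startswith("letter-probability matrix"):
                m = re.search(r"w=\s*(\d+)", line)
                expect = int(m.group(1)) if m else 0
                rows = []
            elif name is not None and line and line[0] in "0123456789.":
                vals = [float(v) for v in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"PFM {name}: matrix row needs 4 values")
                rows.append(vals)
    if name is not None and rows:
        pfms.append(Pfm(name, tf or name, np.array(rows).T))
    if not pfms:
        raise ValueError(f"{path}: no motifs found")
    return pfms


def write_meme_minimal(pfms: list[Pfm], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for p in pfms:
            fh.write(f"MOTIF {p.motif_id} {p.tf_name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} "
                f"nsites= 20 E= 0\n"
            )
            for col in p.matrix.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")
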