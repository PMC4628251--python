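"""Configuration and ground-truth containers for the study simulator."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from sef.core_io.intervals import GenomicInterval

MIN_MOTIF_LENGTH = 7


@dataclass
class GroupSpec:
    """One group of closely related species given by a newick tree.

    Branch lengths are in expected substitutions per neutral site; the
    first leaf encountered in the newick string is the group's reference.
    """

    label: str
    newick: str
    reference: str = ""

    def __post_init__(self) -> None:
        from sef.conservation.models import Phylogeny

        tree = Phylogeny.from_newick(self.newick)
        if not self.reference:
            self.reference = tree.leaf_labels[0]
        if self.reference not in tree.leaf_labels:
            raise ValueError(
                f"reference {self.reference!r} not a leaf of group {self.label}"
            )

    @property
    def species(self) -> list[str]:
        from sef.conservation.models import Phylogeny

        return Phylogeny.from_newick(self.newick).leaf_labels


@dataclass
class PlantedEcrSpec:
    """A conserved element planted inside one intron of every group.

    ``mode`` controls cross-group behaviour: ``resample`` draws an
    independent sequence per group (conserved within, divergent between —
    a true candidate), ``copy`` plants the identical sequence in all groups
    (a decoy that the cross-group filter must remove).
    """

    gene: int  # gene index
    intron: int  # intron index within the gene (0-based)
    length: int = 200
    offset: int | None = None  # start within the intron; centered if None
    scale: float = 0.3  # within-group branch scaling
    mode: str = "resample"

    def __post_init__(self) -> None:
        if self.mode not in ("resample", "copy"):
            raise ValueError(f"unknown cross-group mode {self.mode!r}")
        if self.length <= 0 or not 0 < self.scale < 1:
            raise ValueError("need length > 0 and 0 < scale < 1")


@dataclass
class PlantedMotifSpec:
    """An exact n-mer planted inside a planted ECR in every group.

    ``offsets`` maps group label -> start offset within that group's copy
    of the ECR (one shared int allowed); planted positions are frozen
    against mutation so the string survives verbatim in every leaf.
    """

    ecr: int  # index into SimulationConfig.planted_ecrs
    sequence: str
    offsets: dict[str, int] | int = 0
    strands: dict[str, str] | str = "+"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < MIN_MOTIF_LENGTH:
            raise ValueError(
                f"planted motif must be >= {MIN_MOTIF_LENGTH} bp, "
                f"got {len(self.sequence)}"
            )
        if set(self.sequence) - set("ACGT"):
            raise ValueError("motif must be over ACGT")

    def offset_for(self, group: str) -> int:
        if isinstance(self.offsets, dict):
            return self.offsets[group]
        return self.offsets

    def strand_for(self, group: str) -> str:
        if isinstance(self.strands, dict):
            return self.strands.get(group, "+")
        return self.strands


@dataclass
class MarkSpec:
    """Histone-mark coverage of planted ECRs in mark-bearing groups."""

    me1_fraction: float = 1.0  # fraction of planted ECRs under an H3K4me1 peak
    me3_fraction: float = 0.0  # fraction additionally under H3K4me3
    groups_with_marks: list[str] = field(default_factory=list)
    peak_padding: int = 20

    def __post_init__(self) -> None:
        for f in (self.me1_fraction, self.me3_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("mark fractions must be in [0, 1]")


@dataclass
class SimulationConfig:
    groups: list[GroupSpec] = field(default_factory=list)
    n_genes: int = 5
    exons_per_gene: int = 3
    exon_length: int = 150
    intron_length: int = 1000
    spacer_length: int = 200
    planted_ecrs: list[PlantedEcrSpec] = field(default_factory=list)
    planted_motifs: list[PlantedMotifSpec] = field(default_factory=list)
    mark_spec: MarkSpec = field(default_factory=MarkSpec)
    subst_family: str = "JC69"
    exon_scale: float = 0.05  # within-group branch scaling on exons
    intergroup_exon_divergence: float = 0.15  # subs/site master -> group root
    indel_rate: float = 0.0  # events per site per unit branch length
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.exons_per_gene < 1:
            raise ValueError("need >= 1 gene with >= 1 exon")
        for ecr in self.planted_ecrs:
            if ecr.length > self.intron_length:
                raise ValueError(
                    f"planted ECR of {ecr.length} bp does not fit in a "
                    f"{self.intron_length} bp intron"
                )
            if not (0 <= ecr.gene < self.n_genes):
                raise ValueError(f"ECR gene index {ecr.gene} out of range")
            if not (0 <= ecr.intron < self.exons_per_gene - 1):
                raise ValueError(f"ECR intron index {ecr.intron} out of range")
        for m in self.planted_motifs:
            if not (0 <= m.ecr < len(self.planted_ecrs)):
                raise ValueError(f"motif references unknown ECR {m.ecr}")
            target = self.planted_ecrs[m.ecr]
            for g in self.groups:
                if m.offset_for(g.label) + len(m.sequence) > target.length:
                    raise ValueError(
                        f"motif {m.sequence} overflows ECR {m.ecr} in group "
                        f"{g.label}"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["groups"] = [GroupSpec(**g) for g in raw.get("groups", [])]
        raw["planted_ecrs"] = [
            PlantedEcrSpec(**e) for e in raw.get("planted_ecrs", [])
        ]
        raw["planted_motifs"] = [
            PlantedMotifSpec(**m) for m in raw.get("planted_motifs", [])
        ]
        if "mark_spec" in raw:
            raw["mark_spec"] = MarkSpec(**raw["mark_spec"])
        return cls(**raw)


@dataclass
class TruthTable:
    """Planted ground truth emitted next to the simulated bundle."""

    # ECR index -> species -> interval (only for mode == resample, the true
    # positives; decoys are under decoy_ecrs)
    ecrs: dict[int, dict[str, GenomicInterval]] = field(default_factory=dict)
    decoy_ecrs: dict[int, dict[str, GenomicInterval]] = field(default_factory=dict)
    # motif index -> species -> (interval, strand)
    motifs: dict[int, dict[str, tuple[GenomicInterval, str]]] = field(
        default_factory=dict
    )
    # (gene, intron) -> species -> interval
    introns: dict[tuple[int, int], dict[str, GenomicInterval]] = field(
        default_factory=dict
    )
    # construct id -> {(tissue, time_hpf): true activity rate}
    construct_activity: dict[str, dict[tuple[str, int], float]] = field(
        default_factory=dict
    )
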