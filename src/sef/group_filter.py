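"""Cross-group subtraction of conserved regions.

Two filters: (a) a 1 bp-overlap test against inter-reference pairwise
alignments, and (b) a seed-and-extend local homology search of each ECR
against the other groups' reference genomes with minScore 30 /
minIdentity 50, approximating a BLAT verification pass.
"""

from __future__ import annotations

from dataclasses import dataclass

from sef.conservation.hmm import ConservedRegion
from sef.core_io.alignments import PairwiseAlignment
from sef.core_io.intervals import GenomicInterval

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class HomologySearchConfig:
    min_score: int = 30
    min_identity: float = 50.0  # percent
    word_size: int = 11
    max_gap: int = 100
    x_drop: int = 10

    def __post_init__(self) -> None:
        if self.min_score <= 0:
            raise ValueError("min_score must be > 0")
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")


@dataclass
class HomologyHit:
    query: GenomicInterval
    target: GenomicInterval
    matches: int
    mismatches: int
    gap_openings: int
    strand: str = "+"

    @property
    def score(self) -> int:
        return self.matches - self.mismatches - self.gap_openings

    @property
    def identity(self) -> float:
        aligned = self.matches + self.mismatches
        return 100.0 * self.matches / aligned if aligned else 0.0


def remove_aligned(
    ecrs: list[ConservedRegion],
    inter_group_alns: list[PairwiseAlignment],
) -> tuple[list[ConservedRegion], list[ConservedRegion]]:
    """Partition ECRs by 1 bp overlap with any inter-group aligned block.

    An ECR is removed iff at least one of its reference bases lies inside
    an aligned block (query or target side, matched by assembly).  The
    operation is idempotent and order-independent.
    """
    kept: list[ConservedRegion] = []
    removed: list[ConservedRegion] = []
    for ecr in ecrs:
        hit = False
        for aln in inter_group_alns:
            for block in aln.blocks:
                for side in (block.query, block.target):
                    if ecr.interval.overlap_length(side) >= 1:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                break
        if hit:
            removed.append(ecr.with_flag("intergroup-removed"))
        else:
            kept.append(ecr)
    return kept, removed


def homology_search(
    query: str,
    target_genome: dict[str, str],
    cfg: HomologySearchConfig | None = None,
    query_interval: GenomicInterval | None = None,
    target_assembly: str = "",
) -> list[HomologyHit]:
    """Seed-and-extend search of ``query`` against a genome, both strands.

    Exact ``word_size`` seeds are grouped per diagonal, extended ungapped
    with +1 match / -1 mismatch until the score drops ``x_drop`` below its
    maximum, and hits on gap-compatible diagonals (offset <= ``max_gap``)
    are chained with one gap opening each.  Hits pass iff score >=
    ``min_score`` and identity >= ``min_identity``.
    """
    cfg = cfg or HomologySearchConfig()
    query = query.upper()
    if len(query) < cfg.word_size:
        raise ValueError(
            f"query of {len(query)} bp shorter than word size {cfg.word_size}"
        )
    hits: list[HomologyHit] = []
    qiv = query_interval or GenomicInterval("query", "query", 0, len(query))
    for chrom, tseq in sorted(target_genome.items()):
        tseq = tseq.upper()
        if len(tseq) < cfg.word_size:
            continue
        index = _kmer_index(tseq, cfg.word_size)
        for strand in ("+", "-"):
            q = query if strand == "+" else _revcomp(query)
            raw = _extend_on_diagonals(q, tseq, index, cfg)
            chained = _chain(raw, cfg)
            for qs, qe, ts, te, match, mism, gaps in chained:
                hit = _orient_hit(
                    qs, qe, ts, te, match, mism, gaps, strand, len(query),
                    qiv, chrom, target_assembly,
                )
                if (
                    hit.score >= cfg.min_score
                    and hit.identity >= cfg.min_identity
                ):
                    hits.append(hit)
    return _dedupe(hits)


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def _extend_on_diagonals(
    q: str, t: str, index: dict[str, list[int]], cfg: HomologySearchConfig
) -> list[tuple[int, int, int, int, int, int, int]]:
    """Ungapped X-drop extensions, one per seeded diagonal region."""
    k = cfg.word_size
    seeds_by_diag: dict[int, list[int]] = {}
    for qpos in range(len(q) - k + 1):
        for tpos in index.get(q[qpos : qpos + k], ()):
            seeds_by_diag.setdefault(tpos - qpos, []).append(qpos)
    out = []
    for diag, qstarts in seeds_by_diag.items():
        covered_until = -1
        for qpos in sorted(qstarts):
            if qpos <= covered_until:
                continue
            qs, qe = _xdrop_extend(q, t, qpos, qpos + k, diag, cfg.x_drop)
            covered_until = qe - 1
            match = sum(
                1 for i in range(qs, qe) if q[i] == t[i + diag]
            )
            mism = (qe - qs) - match
            out.append((qs, qe, qs + diag, qe + diag, match, mism, 0))
    return out


def _xdrop_extend(
    q: str, t: str, seed_start: int, seed_end: int, diag: int, x_drop: int
) -> tuple[int, int]:
    best_s, best_e = seed_start, seed_end
    # right
    score = best = 0
    i = seed_end
    while i < len(q) and 0 <= i + diag < len(t):
        score += 1 if q[i] == t[i + diag] else -1
        if score > best:
            best, best_e = score, i + 1
        if best - score >= x_drop:
            break
        i += 1
    # left
    score = best = 0
    i = seed_start - 1
    while i >= 0 and i + diag >= 0:
        if i + diag >= len(t):
            break
        score += 1 if q[i] == t[i + diag] else -1
        if score > best:
            best, best_s = score, i
        if best - score >= x_drop:
            break
        i -= 1
    return best_s, best_e


def _chain(
    segs: list[tuple[int, int, int, int, int, int, int]],
    cfg: HomologySearchConfig,
) -> list[tuple[int, int, int, int, int, int, int]]:
    """Join collinear segments separated by <= max_gap (one opening each)."""
    segs = sorted(segs)
    out: list[list[int]] = []
    for seg in segs:
        qs, qe, ts, te, match, mism, gaps = seg
        if out:
            last = out[-1]
            q_gap = qs - last[1]
            t_gap = ts - last[3]
            if (
                0 <= q_gap <= cfg.max_gap
                and 0 <= t_gap <= cfg.max_gap
                and q_gap != t_gap  # same diagonal handled by extension
            ):
                last[1], last[3] = qe, te
                last[4] += match
                last[5] += mism
                last[6] += 1
                continue
        out.append(list(seg))
    return [tuple(s) for s in out]


def _orient_hit(
    qs: int,
    qe: int,
    ts: int,
    te: int,
    match: int,
    mism: int,
    gaps: int,
    strand: str,
    qlen: int,
    qiv: GenomicInterval,
    chrom: str,
    target_assembly: str,
) -> HomologyHit:
    if strand == "-":  # positions were on the reverse-complemented query
        qs, qe = qlen - qe, qlen - qs
    return HomologyHit(
        query=GenomicInterval(
            qiv.assembly, qiv.chrom, qiv.start + qs, qiv.start + qe
        ),
        target=GenomicInterval(target_assembly or "target", chrom, ts, te),
        matches=match,
        mismatches=mism,
        gap_openings=gaps,
        strand=strand,
    )


def _dedupe(hits: list[HomologyHit]) -> list[HomologyHit]:
    seen = set()
    out = []
    for h in sorted(
        hits, key=lambda h: (-h.score, h.target.chrom, h.target.start)
    ):
        key = (h.query.start, h.query.end, h.target.chrom, h.target.start, h.target.end, h.strand)
        if key not in seen:
            seen.add(key)
            out.append(h)
    return out


def remove_homologous(
    ecrs: list[ConservedRegion],
    sequences: dict[str, str],  # ECR id/str(interval) -> query sequence
    other_genomes: list[dict[str, str]],
    cfg: HomologySearchConfig | None = None,
) -> tuple[list[ConservedRegion], list[ConservedRegion]]:
    """Remove ECRs with >= 1 homology hit in any other reference genome."""
    cfg = cfg or HomologySearchConfig()
    kept, removed = [], []
    for ecr in ecrs:
        seq = sequences[str(ecr.interval)]
        found = False
        if len(seq) >= cfg.word_size:
            for genome in other_genomes:
                if homology_search(seq, genome, cfg, ecr.interval):
                    found = True
                    break
        if found:
            removed.append(ecr.with_flag("intergroup-removed"))
        else:
            kept.append(ecr)
    return kept, removed
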