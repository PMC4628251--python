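"""Shared short-motif discovery across three species' enhancer sequences.

Finds maximal exact matches (n >= 7, both strands) between repeat-masked
sequences, intersects zebrafish-mouse and zebrafish-human hits on
zebrafish coordinates, computes Karlin-Altschul-style chance statistics
with the heptamer bitscore, and annotates shared n-mers with PFM matches
by mean per-column Euclidean distance and a permutation E-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from sef.core_io.formats import Pfm
from sef.core_io.intervals import GenomicInterval
from sef.core_io.mapping import map_interval
from sef.core_io.alignments import PairwiseAlignment

logger = logging.getLogger(__name__)

MIN_N = 7
HEPTAMER_BITSCORE = 13.9

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Simple-repeat masking


@dataclass
class MaskedRun:
    start: int
    end: int
    unit: int


def mask_simple_repeats(
    seq: str,
    max_unit: int = 6,
    min_span: int = 12,
    min_copies: float = 2.5,
) -> tuple[str, list[MaskedRun]]:
    """Lower-case mask tandem repeats (unit 1..max_unit, span >= min_span,
    >= min_copies copies).  Masked bases cannot seed or be contained in
    exact hits."""
    n = len(seq)
    s = seq.upper()
    masked = np.zeros(n, dtype=bool)
    runs: list[MaskedRun] = []
    for unit in range(1, max_unit + 1):
        j = unit
        while j < n:
            if s[j] == s[j - unit]:
                run_start = j
                while j < n and s[j] == s[j - unit]:
                    j += 1
                span = (j - run_start) + unit
                if span >= min_span and span / unit >= min_copies:
                    lo, hi = run_start - unit, j
                    masked[lo:hi] = True
                    runs.append(MaskedRun(lo, hi, unit))
            else:
                j += 1
    out = "".join(c.lower() if masked[i] else c.upper() for i, c in enumerate(s))
    runs.sort(key=lambda r: (r.start, r.end))
    return out, runs


# ---------------------------------------------------------------------------
# Exact maximal matches


@dataclass(frozen=True)
class NmerHit:
    """A maximal exact match between two sequences.

    Coordinates are offsets into the two input sequences; for strand '-'
    the match is between seq A and the reverse complement of seq B, and
    ``start_b:end_b`` is the forward-strand span on B.
    """

    sequence: str  # as read on sequence A
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end_a - self.start_a

    def b_position_of(self, a_pos: int) -> int:
        """Forward-strand B coordinate matching A coordinate ``a_pos``."""
        if not self.start_a <= a_pos < self.end_a:
            raise IndexError("position outside hit")
        if self.strand == "+":
            return self.start_b + (a_pos - self.start_a)
        return self.start_b + (self.end_a - 1 - a_pos)


def _valid(c: str) -> bool:
    return c.isupper() and c in "ACGT"


def _maximal_matches(a: str, b: str, min_n: int) -> list[tuple[int, int, int]]:
    """(start_a, start_b, length) of maximal exact matches of valid bases."""
    if len(a) < min_n or len(b) < min_n:
        return []
    index: dict[str, list[int]] = {}
    for j in range(len(b) - min_n + 1):
        w = b[j : j + min_n]
        if all(_valid(c) for c in w):
            index.setdefault(w, []).append(j)
    seen: set[tuple[int, int]] = set()
    out = []
    for i in range(len(a) - min_n + 1):
        w = a[i : i + min_n]
        if not all(_valid(c) for c in w):
            continue
        for j in index.get(w, ()):
            # extend left
            s_a, s_b = i, j
            while s_a > 0 and s_b > 0 and _valid(a[s_a - 1]) and _valid(b[s_b - 1]) and a[s_a - 1] == b[s_b - 1]:
                s_a -= 1
                s_b -= 1
            # extend right
            e_a, e_b = i + min_n, j + min_n
            while (
                e_a < len(a)
                and e_b < len(b)
                and _valid(a[e_a])
                and _valid(b[e_b])
                and a[e_a] == b[e_b]
            ):
                e_a += 1
                e_b += 1
            key = (s_a, s_b)
            if key not in seen:
                seen.add(key)
                out.append((s_a, s_b, e_a - s_a))
    return out


def find_exact_hits(seq_a: str, seq_b: str, min_n: int = MIN_N) -> list[NmerHit]:
    """All maximal exact matches of length >= min_n, both orientations.

    Inputs should be repeat-masked (lower-case bases are excluded).
    Maximality is per orientation: a hit is not extendable on either side.
    """
    hits: list[NmerHit] = []
    for s_a, s_b, length in _maximal_matches(seq_a, seq_b, min_n):
        hits.append(
            NmerHit(seq_a[s_a : s_a + length].upper(), s_a, s_a + length, s_b, s_b + length, "+")
        )
    rc_b = revcomp(seq_b)
    for s_a, s_rc, length in _maximal_matches(seq_a, rc_b, min_n):
        fwd_start = len(seq_b) - (s_rc + length)
        hits.append(
            NmerHit(
                seq_a[s_a : s_a + length].upper(),
                s_a,
                s_a + length,
                fwd_start,
                fwd_start + length,
                "-",
            )
        )
    hits.sort(key=lambda h: (h.start_a, h.end_a, h.strand, h.start_b))
    return hits


# ---------------------------------------------------------------------------
# Three-way intersection


@dataclass
class PfmMatch:
    motif_id: str
    tf_name: str
    distance: float
    p_value: float
    e_value: float
    query_span: tuple[int, int]  # aligned span on the query n-mer
    strand: str


@dataclass
class SharedMotif:
    """An n-mer present in all three species (modulo strand)."""

    sequence: str
    locations: dict[str, tuple[int, int, str]]  # species -> (start, end, strand)
    pfm_matches: list[PfmMatch] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)


def extract_corresponding_sequence(
    interval: GenomicInterval,
    aln: PairwiseAlignment,
    target_genome: dict[str, str],
) -> tuple[str, GenomicInterval] | None:
    """Map an interval through a pairwise alignment and pull the target
    sequence; returns None (with a notice) when unmappable."""
    mapped = map_interval(interval, aln)
    if mapped is None:
        logger.info("interval %s unmappable through alignment", interval)
        return None
    seq = target_genome[mapped.chrom][mapped.start : mapped.end]
    return seq, mapped


def intersect_threeway(
    hits_ab: list[NmerHit],
    seq_a: str,
    seq_c: str,
    min_n: int = MIN_N,
    species: tuple[str, str, str] = ("zf", "mm", "hs"),
) -> list[SharedMotif]:
    """Overlap A-B hits with freshly computed A-C hits on A coordinates.

    The shared string is the overlapping A substring (length >= min_n);
    B and C locations follow from the hit offsets, strand-aware.
    """
    sp_a, sp_b, sp_c = species
    hits_ac = find_exact_hits(seq_a, seq_c, min_n)
    seen: set[tuple] = set()
    shared: list[SharedMotif] = []
    for h1 in hits_ab:
        for h2 in hits_ac:
            lo = max(h1.start_a, h2.start_a)
            hi = min(h1.end_a, h2.end_a)
            if hi - lo < min_n:
                continue
            loc_b = _sub_location(h1, lo, hi)
            loc_c = _sub_location(h2, lo, hi)
            key = (lo, hi, loc_b, loc_c)
            if key in seen:
                continue
            seen.add(key)
            shared.append(
                SharedMotif(
                    sequence=seq_a[lo:hi].upper(),
                    locations={
                        sp_a: (lo, hi, "+"),
                        sp_b: loc_b,
                        sp_c: loc_c,
                    },
                )
            )
    shared.sort(key=lambda m: (m.locations[sp_a][0], m.locations[sp_a][1]))
    return shared


def _sub_location(hit: NmerHit, lo: int, hi: int) -> tuple[int, int, str]:
    if hit.strand == "+":
        s = hit.start_b + (lo - hit.start_a)
        return (s, s + (hi - lo), "+")
    s = hit.start_b + (hit.end_a - hi)
    return (s, s + (hi - lo), "-")


# ---------------------------------------------------------------------------
# Chance statistics


@dataclass
class ChanceModel:
    """Karlin-Altschul-style expectations for shared n-mer counts.

    E_i = m_i * n_i * 2**(-B) per sequence pair; the chance fraction f is
    the mean of min(E_i / O_i, 1); the probability that the same n-mer is
    shared by chance in both pairwise comparisons is f**2.
    """

    bitscore: float
    expected: list[float]
    observed: list[int]
    fraction: float
    p_joint: float

    def expected_shared(self, shared_count: int) -> float:
        return self.p_joint * shared_count


def expected_chance_alignments(m: int, n: int, bitscore: float = HEPTAMER_BITSCORE) -> float:
    """E = m * n * 2**(-B)."""
    if m < 0 or n < 0:
        raise ValueError("sequence lengths must be >= 0")
    return m * n * 2.0 ** (-bitscore)


def chance_statistics(
    pair_lengths: list[tuple[int, int]],
    observed: list[int],
    bitscore: float = HEPTAMER_BITSCORE,
) -> ChanceModel:
    if len(pair_lengths) != len(observed):
        raise ValueError("pair_lengths and observed must have equal length")
    expected = [expected_chance_alignments(m, n, bitscore) for m, n in pair_lengths]
    ratios = []
    for e, o in zip(expected, observed):
        if o < 0:
            raise ValueError("observed counts must be >= 0")
        if o == 0:
            if e > 0:
                logger.warning("observed count 0 with expected %.2f; ratio capped at 1", e)
            ratios.append(1.0 if e > 0 else 0.0)
        else:
            ratios.append(min(e / o, 1.0))
    f = float(np.mean(ratios)) if ratios else 0.0
    return ChanceModel(bitscore, expected, list(observed), f, f * f)


# ---------------------------------------------------------------------------
# PFM matching


@dataclass
class MotifMatchConfig:
    e_threshold: float = 0.1
    null_permutations: int = 10_000
    min_n: int = MIN_N
    seed: int = 0

    def __post_init__(self) -> None:
        if self.e_threshold <= 0:
            raise ValueError("E threshold must be > 0")
        if self.null_permutations < 1000:
            raise ValueError("need >= 1000 null permutations")


def _one_hot(seq: str) -> np.ndarray:
    mat = np.zeros((4, len(seq)))
    for i, c in enumerate(seq.upper()):
        mat["ACGT".index(c), i] = 1.0
    return mat


def _revcomp_matrix(mat: np.ndarray) -> np.ndarray:
    return mat[::-1, ::-1]


def _best_distance(query: np.ndarray, pfm: np.ndarray) -> tuple[float, tuple[int, int], str]:
    """Minimum mean per-aligned-column Euclidean distance over offsets and
    strands; the aligned span is the full width of the shorter matrix."""
    best = (np.inf, (0, query.shape[1]), "+")
    for strand in ("+", "-"):
        p = pfm if strand == "+" else _revcomp_matrix(pfm)
        nq, np_ = query.shape[1], p.shape[1]
        w = min(nq, np_)
        for off in range(abs(nq - np_) + 1):
            if nq >= np_:
                qw, pw = query[:, off : off + w], p
                span = (off, off + w)
            else:
                qw, pw = query, p[:, off : off + w]
                span = (0, nq)
            d = float(np.sqrt(((qw - pw) ** 2).sum(axis=0)).mean())
            if d < best[0]:
                best = (d, span, strand)
    return best


def _null_distances(
    query: np.ndarray,
    width: int,
    pooled: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Best-distance null from pseudo-PFMs of ``width`` columns drawn from
    the database's pooled column set."""
    cols = pooled[:, rng.integers(0, pooled.shape[1], size=(n_perm, width))]
    # cols shape: (4, n_perm, width) -> (n_perm, 4, width)
    cols = np.transpose(cols, (1, 0, 2))
    nq = query.shape[1]
    w = min(nq, width)
    best = np.full(n_perm, np.inf)
    for mats in (cols, cols[:, ::-1, ::-1]):
        for off in range(abs(nq - width) + 1):
            if nq >= width:
                qw = query[:, off : off + w][None, :, :]
                pw = mats
            else:
                qw = query[None, :, :]
                pw = mats[:, :, off : off + w]
            d = np.sqrt(((qw - pw) ** 2).sum(axis=1)).mean(axis=1)
            best = np.minimum(best, d)
    return best


def match_pfm(
    motif: SharedMotif,
    pfm_db: list[Pfm],
    cfg: MotifMatchConfig | None = None,
) -> SharedMotif:
    """Annotate a shared n-mer with database PFM matches.

    Per PFM: best mean-Euclidean column distance over all offsets/strands;
    p-value from a permutation null (pseudo-PFMs with columns drawn from
    the database's pooled columns, fixed seed); E = p * #PFMs.  Matches
    with E <= threshold are kept; among reported matches at overlapping
    query spans only the smaller-E match survives.
    """
    cfg = cfg or MotifMatchConfig()
    rng = np.random.default_rng(cfg.seed)
    query = _one_hot(motif.sequence)
    usable = []
    for p in pfm_db:
        if p.width < 4:
            logger.warning("PFM %s shorter than 4 columns; skipped", p.motif_id)
            continue
        usable.append(p)
    if not usable:
        motif.pfm_matches = []
        return motif
    pooled = np.concatenate([p.matrix for p in usable], axis=1)
    null_cache: dict[int, np.ndarray] = {}
    candidates: list[PfmMatch] = []
    for p in usable:
        dist, span, strand = _best_distance(query, p.matrix)
        if p.width not in null_cache:
            null_cache[p.width] = _null_distances(
                query, p.width, pooled, cfg.null_permutations, rng
            )
        null = null_cache[p.width]
        p_val = float((1 + (null <= dist + 1e-12).sum()) / (1 + null.size))
        e_val = p_val * len(usable)
        if e_val <= cfg.e_threshold:
            candidates.append(
                PfmMatch(p.motif_id, p.tf_name, dist, p_val, e_val, span, strand)
            )
    motif.pfm_matches = resolve_overlapping_matches(candidates)
    return motif


def resolve_overlapping_matches(matches: list[PfmMatch]) -> list[PfmMatch]:
    """Greedy by ascending E-value: drop any match whose aligned query span
    overlaps an already-kept match."""
    kept: list[PfmMatch] = []
    for m in sorted(matches, key=lambda x: (x.e_value, x.distance, x.motif_id)):
        s, e = m.query_span
        if all(e <= k.query_span[0] or s >= k.query_span[1] for k in kept):
            kept.append(m)
    return kept
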