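"""Two-state phylo-HMM segmentation into conserved regions (ECRs).

State 0 is neutral, state 1 is conserved: the same tree with all branch
lengths multiplied by rho.  Emissions are phylogenetic column likelihoods;
segmentation takes maximal Viterbi runs of the conserved state projected to
reference coordinates, and overlapping calls are resolved by the
longer-region rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from sef.conservation.likelihood import column_likelihoods
from sef.conservation.models import ConservedStateModel, NeutralModel, encode_bases
from sef.core_io.alignments import AlignmentBlock, MultipleAlignment
from sef.core_io.intervals import GenomicInterval

DEFAULT_MIN_ECR_LENGTH = 10


@dataclass
class ConservedRegion:
    """An ECR: interval on the group reference plus provenance flags."""

    interval: GenomicInterval
    score: float  # mean posterior probability of the conserved state
    group: str = ""
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")

    def with_flag(self, flag: str) -> "ConservedRegion":
        return replace(self, flags=self.flags | {flag})


def _block_emissions(
    block: AlignmentBlock, neutral: NeutralModel, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    labels = neutral.tree.leaf_labels
    mat = np.full((len(labels), block.width), -1, dtype=np.int8)
    for row in block.rows:
        if row.species not in neutral.tree.leaf_index:
            raise KeyError(
                f"alignment species {row.species!r} not in neutral tree"
            )
        mat[labels.index(row.species)] = encode_bases(row.text)
    e_neutral = column_likelihoods(mat, neutral.tree, neutral.subst, 1.0)
    e_conserved = column_likelihoods(mat, neutral.tree, neutral.subst, rho)
    return e_neutral, e_conserved


def forward_backward(
    emissions: np.ndarray, csm: ConservedStateModel
) -> tuple[np.ndarray, float]:
    """Posterior state probabilities and total log-likelihood.

    ``emissions`` is (n_cols, 2) of per-column state likelihoods.
    Posteriors of the two states sum to 1 per column.
    """
    n = emissions.shape[0]
    trans = csm.transition_matrix()
    init = csm.initial_distribution()
    alpha = np.zeros((n, 2))
    scale = np.zeros(n)
    a = init * emissions[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, n):
        a = (alpha[t - 1] @ trans) * emissions[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    beta = np.zeros((n, 2))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        b = trans @ (emissions[t + 1] * beta[t + 1])
        beta[t] = b / scale[t + 1]
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post, float(np.log(scale).sum())


def viterbi(emissions: np.ndarray, csm: ConservedStateModel) -> np.ndarray:
    """Most probable state path; 0 = neutral, 1 = conserved."""
    n = emissions.shape[0]
    log_trans = np.log(csm.transition_matrix())
    log_init = np.log(csm.initial_distribution())
    log_emit = np.log(np.maximum(emissions, 1e-300))
    delta = np.zeros((n, 2))
    back = np.zeros((n, 2), dtype=np.int8)
    delta[0] = log_init + log_emit[0]
    for t in range(1, n):
        cand = delta[t - 1][:, None] + log_trans
        back[t] = cand.argmax(axis=0)
        delta[t] = cand.max(axis=0) + log_emit[t]
    path = np.zeros(n, dtype=np.int8)
    path[-1] = delta[-1].argmax()
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def segment_conserved(
    aln: MultipleAlignment,
    neutral: NeutralModel,
    csm: ConservedStateModel,
    min_ecr_length: int = DEFAULT_MIN_ECR_LENGTH,
    group: str = "",
) -> tuple[list[ConservedRegion], list[np.ndarray]]:
    """Call ECRs on the alignment's reference species.

    Each block is an independent HMM chain.  ECRs are maximal Viterbi
    conserved-state runs projected to reference coordinates (columns where
    the reference is gapped stay in the chain but yield no coordinates);
    runs shorter than ``min_ecr_length`` reference bases are dropped.
    Returns the regions and the per-block conserved-state posterior tracks.
    """
    regions: list[ConservedRegion] = []
    posteriors: list[np.ndarray] = []
    for block in aln.blocks:
        ref_row = block.row_for(aln.reference)
        if ref_row is None or block.width == 0:
            posteriors.append(np.zeros(0))
            continue
        e0, e1 = _block_emissions(block, neutral, csm.rho)
        emissions = np.column_stack([e0, e1])
        post, _ = forward_backward(emissions, csm)
        posteriors.append(post[:, 1])
        path = viterbi(emissions, csm)
        ref_pos = _reference_positions(ref_row.text, ref_row.interval.start)
        for s, e in _runs(path == 1):
            cols = ref_pos[s:e]
            covered = cols[cols >= 0]
            if covered.size == 0:
                continue
            start, end = int(covered.min()), int(covered.max()) + 1
            if end - start < min_ecr_length:
                continue
            regions.append(
                ConservedRegion(
                    GenomicInterval(
                        ref_row.interval.assembly,
                        ref_row.interval.chrom,
                        start,
                        end,
                    ),
                    score=float(post[s:e, 1].mean()),
                    group=group,
                )
            )
    return regions, posteriors


def _reference_positions(text: str, start: int) -> np.ndarray:
    """Forward reference coordinate per column; -1 where reference gapped."""
    pos = np.full(len(text), -1, dtype=np.int64)
    cur = start
    for i, c in enumerate(text):
        if c != "-":
            pos[i] = cur
            cur += 1
    return pos


def _runs(mask: np.ndarray):
    """Yield (start, end) of maximal True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    yield from zip(starts.tolist(), ends.tolist())


def resolve_overlaps(
    ecrs: list[ConservedRegion], threshold: float = 0.9
) -> list[ConservedRegion]:
    """Resolve pairs overlapping > ``threshold`` of either region's length.

    The shorter region is dropped; on equal lengths the higher score wins,
    then the leftmost.  Applied transitively until stable; the result is
    independent of input ordering.
    """
    kept = sorted(
        ecrs, key=lambda r: (r.interval.assembly, r.interval.chrom, r.interval.start, r.interval.end)
    )
    changed = True
    while changed:
        changed = False
        drop: set[int] = set()
        for i in range(len(kept)):
            if i in drop:
                continue
            for j in range(i + 1, len(kept)):
                if j in drop:
                    continue
                a, b = kept[i], kept[j]
                if not a.interval.same_sequence(b.interval):
                    break
                if b.interval.start >= a.interval.end:
                    break
                ov = a.interval.overlap_length(b.interval)
                if ov <= threshold * min(a.interval.length, b.interval.length):
                    continue
                loser = _pick_loser(a, b)
                drop.add(i if loser is a else j)
                changed = True
                if loser is a:
                    break
        if drop:
            kept = [r for k, r in enumerate(kept) if k not in drop]
    return kept


def _pick_loser(a: ConservedRegion, b: ConservedRegion) -> ConservedRegion:
    if a.interval.length != b.interval.length:
        return a if a.interval.length < b.interval.length else b
    if a.score != b.score:
        return a if a.score < b.score else b
    return b if a.interval.start <= b.interval.start else a
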