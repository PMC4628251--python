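"""Sequence evolution along a phylogeny with per-site rate scaling.

Substitutions are applied branch by branch from the closed-form transition
matrix, so composed branches obey the model's distance formula exactly.
Indels are optional (off by default: the conservation HMM treats gaps as
missing data) and tracked through column lineages so the true alignment is
known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sef.conservation.models import ALPHABET, Phylogeny, SubstitutionModel
from sef.core_io.alignments import AlignedRow, AlignmentBlock, MultipleAlignment
from sef.core_io.intervals import GenomicInterval


@dataclass
class _NodeSeq:
    bases: np.ndarray  # int8 indices into ACGT
    keys: list[tuple]  # alignment-column lineage keys, lexicographic order
    scales: np.ndarray  # per-site rate multiplier


def _decode(bases: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in bases)


def encode_seq(seq: str) -> np.ndarray:
    lut = {b: i for i, b in enumerate(ALPHABET)}
    try:
        return np.array([lut[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-ACGT base {exc} in root sequence") from exc


def _mutate(
    bases: np.ndarray,
    scales: np.ndarray,
    model: SubstitutionModel,
    t: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Substitute along one branch of length ``t`` (per-site t * scale)."""
    out = bases.copy()
    for s in np.unique(scales):
        if s <= 0 or t * s <= 0:
            continue
        p = model.transition_matrix(t * s)
        sel = np.flatnonzero(scales == s)
        for old in range(4):
            idx = sel[bases[sel] == old]
            if idx.size:
                out[idx] = rng.choice(4, size=idx.size, p=p[old])
    return out


def _apply_indels(
    node: _NodeSeq,
    t: float,
    rate: float,
    rng: np.random.Generator,
    serial: list[int],
) -> _NodeSeq:
    n_events = rng.poisson(rate * t * len(node.bases))
    bases, keys, scales = node.bases, node.keys, node.scales
    for _ in range(n_events):
        if len(bases) < 10:
            break
        pos = int(rng.integers(1, len(bases) - 1))
        size = int(rng.integers(1, 4))
        if rng.random() < 0.5:  # deletion
            size = min(size, len(bases) - pos - 1)
            bases = np.delete(bases, slice(pos, pos + size))
            keys = keys[:pos] + keys[pos + size :]
            scales = np.delete(scales, slice(pos, pos + size))
        else:  # insertion after pos
            ins = rng.integers(0, 4, size=size).astype(np.int8)
            new_keys = []
            for _k in range(size):
                serial[0] += 1
                new_keys.append(keys[pos] + (serial[0],))
            bases = np.concatenate([bases[: pos + 1], ins, bases[pos + 1 :]])
            keys = keys[: pos + 1] + new_keys + keys[pos + 1 :]
            scales = np.concatenate(
                [scales[: pos + 1], np.ones(size), scales[pos + 1 :]]
            )
    return _NodeSeq(bases, keys, scales)


def evolve_on_tree(
    root_seq: str,
    tree: Phylogeny,
    model: SubstitutionModel,
    scale: float = 1.0,
    rng: np.random.Generator | None = None,
    site_scales: np.ndarray | None = None,
    indel_rate: float = 0.0,
    assembly_prefix: str = "",
    chrom: str = "chr1",
) -> tuple[dict[str, str], MultipleAlignment]:
    """Evolve ``root_seq`` down ``tree``; return leaf sequences and the
    true alignment.

    Expected substitutions per site on a branch of length b are
    ``b * scale * site_scales[i]``; sites with scale 0 never mutate
    (used to keep planted motifs verbatim).
    """
    if not root_seq:
        raise ValueError("root sequence must be non-empty")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    rng = rng if rng is not None else np.random.default_rng()
    bases = encode_seq(root_seq)
    scales = (
        np.ones(len(bases))
        if site_scales is None
        else np.asarray(site_scales, dtype=float)
    )
    if scales.shape != bases.shape:
        raise ValueError("site_scales length != root sequence length")
    serial = [0]
    node_seqs: dict[int, _NodeSeq] = {
        tree.root: _NodeSeq(bases, [(i,) for i in range(len(bases))], scales)
    }
    # walk parents before children (reverse post-order)
    parent = {}
    for node in tree.postorder:
        for c in tree.children[node]:
            parent[c] = node
    for node in reversed(tree.postorder):
        if node == tree.root:
            continue
        src = node_seqs[parent[node]]
        t = float(tree.branch_lengths[node]) * scale
        mutated = _mutate(src.bases, src.scales, model, t, rng)
        cur = _NodeSeq(mutated, src.keys, src.scales)
        if indel_rate > 0 and t > 0:
            cur = _apply_indels(cur, t, indel_rate, rng, serial)
        node_seqs[node] = cur

    leaf_seqs = {
        lab: _decode(node_seqs[i].bases) for i, lab in enumerate(tree.leaf_labels)
    }
    alignment = _true_alignment(
        {lab: node_seqs[i] for i, lab in enumerate(tree.leaf_labels)},
        assembly_prefix,
        chrom,
        reference=tree.leaf_labels[0],
    )
    return leaf_seqs, alignment


def _true_alignment(
    leaves: dict[str, _NodeSeq], assembly_prefix: str, chrom: str, reference: str
) -> MultipleAlignment:
    all_keys = sorted({k for ns in leaves.values() for k in ns.keys})
    col_of = {k: i for i, k in enumerate(all_keys)}
    rows = []
    for label, ns in leaves.items():
        text = ["-"] * len(all_keys)
        for k, b in zip(ns.keys, ns.bases):
            text[col_of[k]] = ALPHABET[b]
        rows.append(
            AlignedRow(
                species=assembly_prefix + label,
                interval=GenomicInterval(
                    assembly_prefix + label, chrom, 0, len(ns.bases)
                ),
                strand="+",
                text="".join(text),
                src_size=len(ns.bases),
            )
        )
    return MultipleAlignment([AlignmentBlock(rows)], reference=assembly_prefix + reference)
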