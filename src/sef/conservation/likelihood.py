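"""Column likelihoods by Felsenstein pruning and neutral-model fitting."""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize

from sef.conservation.models import (
    BASE_INDEX,
    NeutralModel,
    Phylogeny,
    SubstitutionModel,
    encode_bases,
)

MIN_FIT_COLUMNS = 500
_MIN_BRANCH = 1e-8
_MAX_BRANCH = 10.0


def column_matrix(
    columns: list[dict[str, str]], leaf_labels: list[str]
) -> np.ndarray:
    """Encode per-leaf base dicts into an (n_leaves, n_cols) index matrix.

    Absent leaves, gaps and Ns become -1 (missing data, marginalized).
    """
    mat = np.full((len(leaf_labels), len(columns)), -1, dtype=np.int8)
    for j, col in enumerate(columns):
        for label, base in col.items():
            if label not in leaf_labels:
                raise KeyError(f"unknown leaf label {label!r}")
            mat[leaf_labels.index(label), j] = BASE_INDEX.get(base.upper(), -1)
    return mat


def column_likelihoods(
    mat: np.ndarray,
    tree: Phylogeny,
    subst: SubstitutionModel,
    scale: float = 1.0,
) -> np.ndarray:
    """Likelihood of every column under the model with branches x ``scale``.

    ``mat`` is (n_leaves, n_cols), entries in {-1, 0..3}; -1 marginalized.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    n_cols = mat.shape[1]
    if mat.shape[0] != tree.n_leaves:
        raise ValueError("column matrix row count != number of tree leaves")
    partial = np.empty((tree.n_nodes, n_cols, 4))
    for leaf in range(tree.n_leaves):
        p = np.zeros((n_cols, 4))
        obs = mat[leaf]
        missing = obs < 0
        p[missing, :] = 1.0
        present = ~missing
        p[present, obs[present]] = 1.0
        partial[leaf] = p
    trans = {
        node: subst.transition_matrix(tree.branch_lengths[node] * scale)
        for node in range(tree.n_nodes)
        if node != tree.root
    }
    for node in tree.postorder:
        if node < tree.n_leaves:
            continue
        acc = np.ones((n_cols, 4))
        for child in tree.children[node]:
            acc *= partial[child] @ trans[child].T
        partial[node] = acc
    return partial[tree.root] @ subst.pi


def prune_likelihood(
    column: dict[str, str],
    model: NeutralModel,
    scale: float = 1.0,
) -> float:
    """Probability of one alignment column: sum over root states of
    pi(x) * L(x), computed by post-order pruning; missing leaves are
    marginalized (an all-missing column has likelihood 1)."""
    mat = column_matrix([column], model.tree.leaf_labels)
    return float(column_likelihoods(mat, model.tree, model.subst, scale)[0])


def _collapse_patterns(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    return patterns, counts.astype(float)


def log_likelihood(
    mat: np.ndarray, tree: Phylogeny, subst: SubstitutionModel, scale: float = 1.0
) -> float:
    patterns, counts = _collapse_patterns(mat)
    liks = column_likelihoods(patterns, tree, subst, scale)
    return float(np.dot(counts, np.log(np.maximum(liks, 1e-300))))


def fit_neutral(
    mat: np.ndarray,
    topology: Phylogeny,
    family: str = "JC69",
    chrom_class: str = "autosome",
    min_columns: int = MIN_FIT_COLUMNS,
) -> NeutralModel:
    """Maximum-likelihood branch lengths (and kappa, pi for HKY85) on a
    fixed topology, fitted to putatively neutral alignment columns.

    Deterministic: optimization starts from branch lengths of 0.1 and
    kappa 2.0.  Columns with identical bases everywhere drive branch
    lengths to the lower boundary (a warning is emitted).
    """
    if mat.shape[1] < min_columns:
        raise ValueError(
            f"need >= {min_columns} columns to fit a neutral model, "
            f"got {mat.shape[1]}"
        )
    if mat.shape[0] != topology.n_leaves:
        raise ValueError("column matrix rows != topology leaves")

    if family == "HKY85":
        obs = mat[mat >= 0]
        freqs = np.bincount(obs, minlength=4).astype(float)
        pi = freqs / freqs.sum() if freqs.sum() else np.full(4, 0.25)
        pi = np.clip(pi, 1e-4, None)
        pi /= pi.sum()
    else:
        pi = np.full(4, 0.25)

    free = [n for n in range(topology.n_nodes) if n != topology.root]
    patterns, counts = _collapse_patterns(mat)
    fit_kappa = family == "HKY85"

    def unpack(x: np.ndarray) -> tuple[Phylogeny, SubstitutionModel]:
        lengths = np.zeros(topology.n_nodes)
        lengths[free] = x[: len(free)]
        kappa = float(x[len(free)]) if fit_kappa else 1.0
        tree = topology.with_branch_lengths(lengths)
        return tree, SubstitutionModel(family=family, pi=pi, kappa=kappa)

    def neg_loglik(x: np.ndarray) -> float:
        tree, subst = unpack(x)
        liks = column_likelihoods(patterns, tree, subst)
        return -float(np.dot(counts, np.log(np.maximum(liks, 1e-300))))

    x0 = np.full(len(free), 0.1)
    bounds = [(_MIN_BRANCH, _MAX_BRANCH)] * len(free)
    if fit_kappa:
        x0 = np.append(x0, 2.0)
        bounds.append((0.05, 100.0))
    res = minimize(neg_loglik, x0, method="L-BFGS-B", bounds=bounds)
    tree, subst = unpack(res.x)
    if tree.total_length < len(free) * 1e-5:
        warnings.warn(
            "fitted branch lengths at lower boundary; columns may be "
            "invariant",
            stacklevel=2,
        )
    return NeutralModel(tree, subst, chrom_class)


def columns_from_texts(texts: dict[str, str]) -> np.ndarray:
    """Stack equal-length gapped row texts into a column index matrix.

    Row order follows the dict insertion order; returns labels implicitly —
    use with :func:`column_likelihoods` via a matching leaf order.
    """
    rows = [encode_bases(t) for t in texts.values()]
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise ValueError("row texts have unequal lengths")
    return np.vstack(rows)
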