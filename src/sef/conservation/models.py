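"""Phylogenetic trees, nucleotide substitution models and HMM state models."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from scipy.linalg import expm

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


class Phylogeny:
    """Rooted tree with branch lengths, indexed for post-order computation.

    Node 0..n_leaves-1 are leaves (in ``leaf_labels`` order); internal nodes
    follow in post-order, the root last.
    """

    def __init__(
        self,
        leaf_labels: list[str],
        children: list[list[int]],
        branch_lengths: np.ndarray,
    ) -> None:
        self.leaf_labels = list(leaf_labels)
        self.children = children
        self.branch_lengths = np.asarray(branch_lengths, dtype=float)
        if np.any(self.branch_lengths < 0):
            raise ValueError("branch lengths must be >= 0")
        self.n_leaves = len(leaf_labels)
        self.n_nodes = len(children)
        self.root = self.n_nodes - 1
        self.leaf_index = {lab: i for i, lab in enumerate(leaf_labels)}
        # post-order: children always precede parents by construction
        self.postorder = list(range(self.n_nodes))

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=text, schema="newick")
        leaves = [lf for lf in tree.leaf_node_iter()]
        leaf_labels = [lf.taxon.label.replace(" ", "_") for lf in leaves]
        index: dict[int, int] = {}
        for i, lf in enumerate(leaves):
            index[id(lf)] = i
        children: list[list[int]] = [[] for _ in leaves]
        lengths: list[float] = [lf.edge.length or 0.0 for lf in leaves]
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                continue
            kid_idx = [index[id(c)] for c in node.child_nodes()]
            index[id(node)] = len(children)
            children.append(kid_idx)
            lengths.append(node.edge.length or 0.0)
        return cls(leaf_labels, children, np.array(lengths))

    def to_newick(self) -> str:
        def fmt(node: int) -> str:
            if node < self.n_leaves:
                return f"{self.leaf_labels[node]}:{self.branch_lengths[node]:.8g}"
            inner = ",".join(fmt(c) for c in self.children[node])
            if node == self.root:
                return f"({inner})"
            return f"({inner}):{self.branch_lengths[node]:.8g}"

        return fmt(self.root) + ";"

    def with_branch_lengths(self, lengths: np.ndarray) -> "Phylogeny":
        return Phylogeny(self.leaf_labels, self.children, np.asarray(lengths))

    def scaled(self, factor: float) -> "Phylogeny":
        return self.with_branch_lengths(self.branch_lengths * factor)

    @property
    def total_length(self) -> float:
        # root edge carries no information in a reversible model
        return float(self.branch_lengths.sum() - self.branch_lengths[self.root])


@dataclass
class SubstitutionModel:
    """JC69 or HKY85 nucleotide substitution model, rate-normalized.

    The rate matrix is scaled so that one unit of branch length equals one
    expected substitution per site at equilibrium.
    """

    family: str = "JC69"
    pi: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    kappa: float = 1.0

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.family not in ("JC69", "HKY85"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family == "JC69":
            self.pi = np.full(4, 0.25)
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must be non-negative and sum to 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")

    def rate_matrix(self) -> np.ndarray:
        pi = self.pi
        q = np.zeros((4, 4))
        # transitions: A<->G (0,2), C<->T (1,3)
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = pi[j]
                if self.family == "HKY85" and {i, j} in ({0, 2}, {1, 3}):
                    rate *= self.kappa
                q[i, j] = rate
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(q)))
        return q / mu

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t): probability of base j after branch length t given base i."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        if self.family == "JC69":
            p_same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
            p_diff = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
            p = np.full((4, 4), p_diff)
            np.fill_diagonal(p, p_same)
            return p
        return expm(self.rate_matrix() * t)


@dataclass
class NeutralModel:
    """Neutral evolution: tree with branch lengths + substitution model."""

    tree: Phylogeny
    subst: SubstitutionModel
    chrom_class: str = "autosome"

    def __post_init__(self) -> None:
        if self.chrom_class not in ("autosome", "X"):
            raise ValueError("chrom_class must be 'autosome' or 'X'")


@dataclass
class ConservedStateModel:
    """Conserved-state parameters of the two-state phylo-HMM.

    Branch lengths of the conserved state are the neutral lengths times
    ``rho``.  Transition probabilities derive from the expected conserved
    element length ``expected_length`` (mu = 1/L) and target coverage
    ``coverage`` (nu = mu * gamma / (1 - gamma)).
    """

    rho: float = 0.3
    expected_length: float = 45.0
    coverage: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise ValueError("rho must be in (0, 1)")
        mu, nu = self.mu, self.nu
        if not (0 < mu < 1 and 0 < nu < 1):
            raise ValueError("derived transition probabilities out of (0,1)")

    @property
    def mu(self) -> float:
        return 1.0 / self.expected_length

    @property
    def nu(self) -> float:
        return self.mu * self.coverage / (1.0 - self.coverage)

    def transition_matrix(self) -> np.ndarray:
        """Rows/cols: state 0 = neutral, state 1 = conserved."""
        mu, nu = self.mu, self.nu
        return np.array([[1 - nu, nu], [mu, 1 - mu]])

    def initial_distribution(self) -> np.ndarray:
        # stationary distribution of the transition matrix
        return np.array([1 - self.coverage, self.coverage])


# ---------------------------------------------------------------------------
# Plain-text model serialization (newick + key: value params)


def write_model(model: NeutralModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"FAMILY: {model.subst.family}\n")
        fh.write("PI: " + " ".join(f"{v:.8g}" for v in model.subst.pi) + "\n")
        fh.write(f"KAPPA: {model.subst.kappa:.8g}\n")
        fh.write(f"CHROM_CLASS: {model.chrom_class}\n")
        fh.write(f"TREE: {model.tree.to_newick()}\n")


def read_model(path: str | Path) -> NeutralModel:
    fields: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if ":" in line:
                key, val = line.split(":", 1)
                fields[key.strip()] = val.strip()
    try:
        subst = SubstitutionModel(
            family=fields["FAMILY"],
            pi=np.array([float(v) for v in fields["PI"].split()]),
            kappa=float(fields["KAPPA"]),
        )
        tree = Phylogeny.from_newick(fields["TREE"])
    except KeyError as exc:
        raise ValueError(f"model file {path} missing field {exc}") from exc
    return NeutralModel(tree, subst, fields.get("CHROM_CLASS", "autosome"))


def encode_bases(bases: str) -> np.ndarray:
    """Map a base string to indices; gaps/N/other -> -1 (missing)."""
    arr = np.full(len(bases), -1, dtype=np.int8)
    for i, b in enumerate(bases.upper()):
        arr[i] = BASE_INDEX.get(b, -1)
    return arr
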