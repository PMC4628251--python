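"""Simulator tests: closed-form divergence, determinism, planted truth."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from sef.conservation.models import Phylogeny, SubstitutionModel
from sef.core_io import parse_maf, read_fasta
from sef.synthetic_data import (
    GroupSpec,
    PlantedEcrSpec,
    PlantedMotifSpec,
    SimulationConfig,
    evolve_on_tree,
    generate_study,
    revcomp,
)


class TestEvolveOnTree:
    def test_zero_branch_lengths_identity(self, rng):
        tree = Phylogeny.from_newick("(A:0.0,B:0.0,C:0.0);")
        root = "".join("ACGT"[i] for i in rng.integers(0, 4, size=500))
        leaves, aln = evolve_on_tree(root, tree, SubstitutionModel("JC69"), rng=rng)
        assert all(s == root for s in leaves.values())
        assert all("-" not in r.text for r in aln.blocks[0].rows)

    def test_jc_closed_form_divergence(self):
        # two-leaf tree, total d = 0.2: mismatch fraction should match
        # p = (3/4)(1 - e^(-4d/3)) within 3 binomial SD at 100 kb
        d = 0.2
        p_expect = 0.75 * (1 - np.exp(-4 * d / 3))
        n = 100_000
        rng = np.random.default_rng(5)
        tree = Phylogeny.from_newick("(A:0.12,B:0.08);")
        root = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
        leaves, _ = evolve_on_tree(root, tree, SubstitutionModel("JC69"), rng=rng)
        mism = sum(a != b for a, b in zip(leaves["A"], leaves["B"])) / n
        sd = np.sqrt(p_expect * (1 - p_expect) / n)
        assert abs(mism - p_expect) <= 3 * sd

    def test_scale_multiplies_branch_lengths(self):
        rng = np.random.default_rng(6)
        tree = Phylogeny.from_newick("(A:1.0,B:1.0);")
        root = "".join("ACGT"[i] for i in rng.integers(0, 4, size=50_000))
        # scale 0.1 -> total d = 0.2
        leaves, _ = evolve_on_tree(root, tree, SubstitutionModel("JC69"), scale=0.1, rng=rng)
        p_expect = 0.75 * (1 - np.exp(-4 * 0.2 / 3))
        mism = sum(a != b for a, b in zip(leaves["A"], leaves["B"])) / 50_000
        assert abs(mism - p_expect) <= 3 * np.sqrt(p_expect * (1 - p_expect) / 50_000)

    def test_masked_sites_do_not_mutate(self, rng):
        tree = Phylogeny.from_newick("(A:0.5,(B:0.6,C:0.7):0.4);")
        root = "".join("ACGT"[i] for i in rng.integers(0, 4, size=200))
        scales = np.ones(200)
        scales[50:70] = 0.0
        leaves, _ = evolve_on_tree(
            root, tree, SubstitutionModel("JC69"), rng=rng, site_scales=scales
        )
        for seq in leaves.values():
            assert seq[50:70] == root[50:70]

    def test_empty_root_errors(self, rng):
        tree = Phylogeny.from_newick("(A:0.1,B:0.1);")
        with pytest.raises(ValueError):
            evolve_on_tree("", tree, SubstitutionModel("JC69"), rng=rng)

    def test_indels_tracked_in_alignment(self):
        rng = np.random.default_rng(9)
        tree = Phylogeny.from_newick("(A:0.3,B:0.3);")
        root = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))
        leaves, aln = evolve_on_tree(
            root, tree, SubstitutionModel("JC69"), rng=rng, indel_rate=0.01
        )
        block = aln.blocks[0]
        assert len(leaves["A"]) != len(leaves["B"])  # some indel happened
        for row in block.rows:
            ungapped = row.text.replace("-", "")
            assert ungapped == leaves[row.species]


def _dir_hash(path: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(path.rglob("*")):
        if p.is_file():
            h.update(p.relative_to(path).as_posix().encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestGenerateStudy:
    def _small_cfg(self, **kw):
        defaults = dict(
            groups=[
                GroupSpec("g1", "(a1:0.2,(a2:0.15,a3:0.2):0.1);"),
                GroupSpec("g2", "(b1:0.2,b2:0.25,b3:0.2);"),
            ],
            n_genes=2,
            exons_per_gene=3,
            intron_length=600,
            planted_ecrs=[PlantedEcrSpec(0, 0, length=150)],
            planted_motifs=[PlantedMotifSpec(0, "GATTACAG", offsets={"g1": 10, "g2": 50})],
            seed=3,
        )
        defaults.update(kw)
        return SimulationConfig(**defaults)

    def test_null_config(self, tmp_path):
        cfg = self._small_cfg(
            groups=[GroupSpec("g1", "(a1:0.2,a2:0.2);")],
            planted_ecrs=[],
            planted_motifs=[],
        )
        bundle = generate_study(cfg, tmp_path / "null")
        assert bundle.truth.ecrs == {}
        aln = parse_maf(bundle.group_maf["g1"])
        assert len(aln.blocks) == 1

    def test_truth_bookkeeping(self, tmp_path):
        slots = [(0, 0), (0, 1), (1, 0), (1, 1)]
        cfg = self._small_cfg(
            planted_ecrs=[PlantedEcrSpec(g, i, length=120) for g, i in slots],
            planted_motifs=[],
        )
        bundle = generate_study(cfg, tmp_path / "book")
        assert len(bundle.truth.ecrs) == 4
        for idx, per_sp in bundle.truth.ecrs.items():
            spec = cfg.planted_ecrs[idx]
            for sp, iv in per_sp.items():
                intron = bundle.truth.introns[(spec.gene, spec.intron)][sp]
                assert intron.contains(iv)

    def test_determinism_byte_identical(self, tmp_path):
        cfg = self._small_cfg()
        generate_study(cfg, tmp_path / "r1")
        generate_study(cfg, tmp_path / "r2")
        assert _dir_hash(tmp_path / "r1") == _dir_hash(tmp_path / "r2")

    def test_seed_changes_output(self, tmp_path):
        generate_study(self._small_cfg(seed=3), tmp_path / "s3")
        generate_study(self._small_cfg(seed=4), tmp_path / "s4")
        assert _dir_hash(tmp_path / "s3") != _dir_hash(tmp_path / "s4")

    def test_planted_motifs_recoverable_by_string_search(self, bundle, bundle_cfg):
        for mi, per_sp in bundle.truth.motifs.items():
            motif = bundle_cfg.planted_motifs[mi].sequence
            for sp, (iv, strand) in per_sp.items():
                seq = read_fasta(bundle.fasta[sp])["chr1"]
                found = seq[iv.start : iv.end]
                assert found == (motif if strand == "+" else revcomp(motif))

    def test_ecr_overflow_rejected(self):
        with pytest.raises(ValueError):
            self._small_cfg(planted_ecrs=[PlantedEcrSpec(0, 0, length=700)])

    def test_motif_overflow_rejected(self):
        with pytest.raises(ValueError):
            self._small_cfg(
                planted_motifs=[PlantedMotifSpec(0, "GATTACAG", offsets={"g1": 145, "g2": 0})]
            )

    def test_short_motif_rejected(self):
        with pytest.raises(ValueError):
            PlantedMotifSpec(0, "ACGT")

    def test_intergroup_alignment_covers_exons_and_decoys(self, bundle, bundle_cfg):
        pw = next(iter(bundle.inter_alignments.values()))
        n_exons = bundle_cfg.n_genes * bundle_cfg.exons_per_gene
        n_decoys = len(bundle.truth.decoy_ecrs)
        assert len(pw.blocks) == n_exons + n_decoys


def test_yaml_round_trip(tmp_path):
    text = """
groups:
  - label: g1
    newick: "(a1:0.2,a2:0.2);"
  - label: g2
    newick: "(b1:0.2,b2:0.2);"
n_genes: 2
exons_per_gene: 3
intron_length: 500
planted_ecrs:
  - {gene: 0, intron: 0, length: 100}
planted_motifs:
  - {ecr: 0, sequence: GATTACAG, offsets: 5}
seed: 12
"""
    p = tmp_path / "cfg.yaml"
    p.write_text(text)
    cfg = SimulationConfig.from_yaml(p)
    assert [g.label for g in cfg.groups] == ["g1", "g2"]
    assert cfg.planted_ecrs[0].length == 100
    assert cfg.seed == 12
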