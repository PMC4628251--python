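"""Exon matching, projection thresholds and intron derivation."""

import numpy as np
import pandas as pd
import pytest

from sef.core_io.alignments import PairwiseAlignment, PairwiseBlock
from sef.core_io.formats import GeneModel
from sef.core_io.intervals import GenomicInterval
from sef.orthology import (
    ExonMatch,
    OrthologousIntronSet,
    ProjectionConfig,
    derive_introns,
    match_exons,
    project_exon,
)

BASES = "ACGT"


def _seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


def _mutate_at(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


def _identity_alignment(rng, n=1000, qa="spA", ta="spB", mismatches=()):
    q = _seq(rng, n)
    t = _mutate_at(q, mismatches)
    block = PairwiseBlock(
        GenomicInterval(qa, "chr1", 0, n),
        GenomicInterval(ta, "chr1", 0, n),
        q,
        t,
    )
    return PairwiseAlignment([block], qa, ta)


def _gene(species, gid, exon_spans, strand="+"):
    g = GeneModel(
        gid,
        GenomicInterval(species, "chr1", exon_spans[0][0], exon_spans[-1][1], strand),
    )
    g.exons = [GenomicInterval(species, "chr1", s, e, strand) for s, e in exon_spans]
    return g


def _table(**cols):
    return pd.DataFrame({k: [v] for k, v in cols.items()})


class TestMatchExons:
    def test_identity_single_exon(self, rng):
        aln = _identity_alignment(rng)
        a = {"gA": _gene("spA", "gA", [(100, 250)])}
        b = {"gB": _gene("spB", "gB", [(100, 250)])}
        matches = match_exons(a, b, _table(spA="gA", spB="gB"), aln)
        assert len(matches) == 1
        assert matches[0].support == "annotated-both"
        assert matches[0].identity == pytest.approx(1.0)

    def test_unannotated_target_region_no_match(self, rng):
        aln = _identity_alignment(rng)
        a = {"gA": _gene("spA", "gA", [(100, 250)])}
        b = {"gB": _gene("spB", "gB", [(600, 750)])}  # elsewhere
        assert match_exons(a, b, _table(spA="gA", spB="gB"), aln) == []

    def test_low_identity_rejected(self, rng):
        # 60 mismatches over the 150 bp exon -> identity 0.6 < 0.7
        mism = list(range(100, 250, 3))[:60]
        aln = _identity_alignment(rng, mismatches=mism)
        a = {"gA": _gene("spA", "gA", [(100, 250)])}
        b = {"gB": _gene("spB", "gB", [(100, 250)])}
        assert match_exons(a, b, _table(spA="gA", spB="gB"), aln) == []

    def test_missing_gene_skipped_with_warning(self, rng, caplog):
        aln = _identity_alignment(rng)
        a = {"gA": _gene("spA", "gA", [(100, 250)])}
        with caplog.at_level("WARNING"):
            out = match_exons(a, {}, _table(spA="gA", spB="gB"), aln)
        assert out == []
        assert "skipped" in caplog.text


class TestProjectExon:
    def test_full_identity_accepted(self, rng):
        aln = _identity_alignment(rng)
        m = project_exon(GenomicInterval("spA", "chr1", 100, 250), aln)
        assert m is not None
        assert m.support == "projected"
        assert m.identity == pytest.approx(1.0)
        assert (m.exon_b.start, m.exon_b.end) == (100, 250)

    def test_window_identity_065_rejected(self, rng):
        # periodic mismatches: every 100 bp window has identity exactly 0.65
        mism = [p for p in range(100, 300) if p % 20 < 7]
        aln = _identity_alignment(rng, mismatches=mism)
        assert project_exon(GenomicInterval("spA", "chr1", 100, 300), aln) is None

    def test_short_exon_whole_window(self, rng):
        # 80 bp exon, 22 mismatches -> identity 0.725 >= 0.70 accepted
        mism = list(range(100, 180, 4))[:22]
        assert len(mism) == 20  # 80/4 -> 20 mismatches = identity 0.75
        mism = list(range(100, 144, 2))  # 22 mismatches in [100,144)
        aln = _identity_alignment(rng, mismatches=mism)
        m = project_exon(GenomicInterval("spA", "chr1", 100, 180), aln)
        assert m is not None
        assert m.identity == pytest.approx(1 - 22 / 80)

    def test_unmappable_returns_none(self, rng):
        aln = _identity_alignment(rng, n=200)
        assert project_exon(GenomicInterval("spA", "chr1", 500, 600), aln) is None

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ProjectionConfig(identity_threshold=0.0)
        with pytest.raises(ValueError):
            ProjectionConfig(window=0)


def _match(gid_a, gid_b, exon_a, exon_b, sp_a="P", sp_b="B"):
    return ExonMatch(
        gid_a,
        gid_b,
        GenomicInterval(sp_a, "chr1", *exon_a),
        GenomicInterval(sp_b, "chr1", *exon_b),
    )


class TestDeriveIntrons:
    SPANS = [(0, 100), (200, 300), (400, 500)]

    def _annots(self, species_list):
        return {
            sp: {f"g_{sp}": _gene(sp, f"g_{sp}", self.SPANS)} for sp in species_list
        }

    def test_three_exons_two_introns(self):
        annots = self._annots(["P", "B"])
        matches = {
            "B": [_match("g_P", "g_B", span, span) for span in self.SPANS]
        }
        sets = derive_introns(matches, annots, pivot="P")
        assert len(sets) == 2
        assert [(s.introns["P"].start, s.introns["P"].end) for s in sets] == [
            (100, 200),
            (300, 400),
        ]
        assert all(set(s.species) == {"P", "B"} for s in sets)

    def test_unmatched_middle_exon_breaks_bracketing(self):
        annots = self._annots(["P", "B"])
        matches = {
            "B": [
                _match("g_P", "g_B", self.SPANS[0], self.SPANS[0]),
                _match("g_P", "g_B", self.SPANS[2], self.SPANS[2]),
            ]
        }
        assert derive_introns(matches, annots, pivot="P") == []

    def test_extra_exon_in_target_breaks_adjacency(self):
        annots = self._annots(["P"])
        # B has an extra annotated exon between the two matched ones
        b_spans = [(0, 100), (150, 170), (200, 300)]
        annots["B"] = {"g_B": _gene("B", "g_B", b_spans)}
        matches = {
            "B": [
                _match("g_P", "g_B", (0, 100), (0, 100)),
                _match("g_P", "g_B", (200, 300), (200, 300)),
            ]
        }
        # pivot has only 2 exons here
        annots["P"] = {"g_P": _gene("P", "g_P", [(0, 100), (200, 300)])}
        assert derive_introns(matches, annots, pivot="P") == []

    def test_three_species_requires_all(self):
        annots = self._annots(["P", "B", "C"])
        matches = {
            "B": [_match("g_P", "g_B", s, s) for s in self.SPANS],
            "C": [_match("g_P", "g_C", s, s, sp_b="C") for s in self.SPANS[:1]],
        }
        assert derive_introns(matches, annots, pivot="P") == []

    def test_species_relabeling_symmetry(self):
        annots = self._annots(["P", "B", "C"])
        matches = {
            "B": [_match("g_P", "g_B", s, s) for s in self.SPANS],
            "C": [_match("g_P", "g_C", s, s, sp_b="C") for s in self.SPANS],
        }
        sets1 = derive_introns(matches, annots, pivot="P")
        swapped = {"C": matches["B"], "B": matches["C"]}
        # relabel: swap exon_b gene ids to match the new species keys
        swapped = {
            "B": [_match("g_P", "g_B", (m.exon_a.start, m.exon_a.end), (m.exon_b.start, m.exon_b.end)) for m in matches["C"]],
            "C": [_match("g_P", "g_C", (m.exon_a.start, m.exon_a.end), (m.exon_b.start, m.exon_b.end), sp_b="C") for m in matches["B"]],
        }
        sets2 = derive_introns(swapped, annots, pivot="P")
        assert len(sets1) == len(sets2) == 2


class TestSyntheticBundleOracle:
    def test_matches_equal_truth_pairing(self, bundle, bundle_cfg):
        from sef.core_io import read_gff3, read_ortholog_table

        refs = [g.reference for g in bundle_cfg.groups]
        annots = {sp: read_gff3(bundle.gff3[sp], assembly=sp) for sp in refs}
        table = read_ortholog_table(bundle.ortholog_tsv)
        pw = bundle.inter_alignments[(refs[0], refs[1])]
        matches = match_exons(annots[refs[0]], annots[refs[1]], table, pw)
        # every exon of every gene should match its orthologous counterpart
        expected = bundle_cfg.n_genes * bundle_cfg.exons_per_gene
        assert len(matches) == expected
        for m in matches:
            assert (m.exon_a.start, m.exon_a.end) == (m.exon_b.start, m.exon_b.end)

    def test_intron_sets_equal_truth_map(self, bundle, bundle_cfg):
        from sef.core_io import read_gff3, read_ortholog_table

        refs = [g.reference for g in bundle_cfg.groups]
        pivot = refs[0]
        annots = {sp: read_gff3(bundle.gff3[sp], assembly=sp) for sp in refs}
        table = read_ortholog_table(bundle.ortholog_tsv)
        matches = {
            sp: match_exons(
                annots[pivot], annots[sp], table, bundle.inter_alignments[(pivot, sp)]
            )
            for sp in refs[1:]
        }
        sets = derive_introns(matches, annots, pivot=pivot)
        truth = bundle.truth.introns
        assert len(sets) == len(truth)
        got = {
            (s.introns[pivot].start, s.introns[pivot].end) for s in sets
        }
        want = {(d[pivot].start, d[pivot].end) for d in truth.values()}
        assert got == want
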