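"""Shared-motif discovery: masking, exact hits, chance stats, PFM matching."""

import numpy as np
import pytest

from sef.core_io.formats import Pfm
from sef.motif_discovery import (
    HEPTAMER_BITSCORE,
    MotifMatchConfig,
    PfmMatch,
    chance_statistics,
    expected_chance_alignments,
    find_exact_hits,
    intersect_threeway,
    mask_simple_repeats,
    match_pfm,
    resolve_overlapping_matches,
    revcomp,
)

BASES = "ACGT"


def _seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


# ---------------------------------------------------------------------------
# masking


def brute_force_tandem_mask(seq, max_unit=6, min_span=12, min_copies=2.5):
    """Oracle: exhaustive scan over all (start, unit) tandem stretches."""
    n = len(seq)
    s = seq.upper()
    masked = np.zeros(n, dtype=bool)
    for unit in range(1, max_unit + 1):
        for start in range(n - unit):
            end = start + unit
            while end < n and s[end] == s[end - unit]:
                end += 1
            span = end - start
            if span >= min_span and span / unit >= min_copies and span > unit:
                masked[start:end] = True
    return masked


class TestMaskSimpleRepeats:
    def test_dinucleotide_run_fully_masked(self):
        masked, runs = mask_simple_repeats("ACACACACACACAC")
        assert masked == "acacacacacacac"
        assert runs

    def test_no_qualifying_run_unchanged(self):
        masked, runs = mask_simple_repeats("ACGTACGTTGCA")
        assert masked == "ACGTACGTTGCA"
        assert runs == []

    def test_planted_run_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(20)
        seq = _seq(rng, 500) + "AAT" * 6 + _seq(rng, 482)
        masked, _ = mask_simple_repeats(seq)
        want = brute_force_tandem_mask(seq)
        got = np.array([c.islower() for c in masked])
        assert np.array_equal(got, want)
        assert got[500:518].all()

    @pytest.mark.parametrize("seed", range(5))
    def test_random_sequences_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = _seq(rng, 400)
        masked, _ = mask_simple_repeats(seq)
        got = np.array([c.islower() for c in masked])
        assert np.array_equal(got, brute_force_tandem_mask(seq))


# ---------------------------------------------------------------------------
# exact hits


def brute_force_hits(seq_a, seq_b, min_n=7):
    """O(n*m) oracle: all maximal exact matches by direct definition."""
    def valid(c):
        return c.isupper() and c in "ACGT"

    def scan(a, b):
        found = set()
        for i in range(len(a)):
            for j in range(len(b)):
                if i > 0 and j > 0 and valid(a[i - 1]) and valid(b[j - 1]) and a[i - 1] == b[j - 1]:
                    continue  # not left-maximal
                L = 0
                while (
                    i + L < len(a)
                    and j + L < len(b)
                    and valid(a[i + L])
                    and valid(b[j + L])
                    and a[i + L] == b[j + L]
                ):
                    L += 1
                if L >= min_n:
                    found.add((i, j, L))
        return found

    fwd = scan(seq_a, seq_b)
    rc = scan(seq_a, revcomp(seq_b))
    out = set()
    for i, j, L in fwd:
        out.add((i, i + L, j, j + L, "+"))
    for i, j, L in rc:
        s = len(seq_b) - (j + L)
        out.add((i, i + L, s, s + L, "-"))
    return out


class TestFindExactHits:
    def test_identical_unique_sequence_single_hit(self, rng):
        s = "GTACCGTTAGCAATGCCGAT"  # 20 bp, no internal repeats
        hits = find_exact_hits(s, s)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1
        assert fwd[0].length == 20

    def test_reverse_strand_hit(self):
        a = "AAAAAAAAAA" + "GATTACAG" + "AAAAAAAAAA"
        b = "AAAAAAAAAA" + revcomp("GATTACAG") + "AAAAAAAAAA"
        hits = find_exact_hits(a, b, min_n=7)
        rc_hits = [h for h in hits if h.strand == "-" and h.sequence == "GATTACAG"]
        assert rc_hits
        h = rc_hits[0]
        assert (h.start_a, h.end_a) == (10, 18)
        assert b[h.start_b : h.end_b] == revcomp("GATTACAG")

    def test_masked_bases_cannot_participate(self):
        a = "GGGGG" + "gattacag" + "TTTTT"
        b = "AAAAA" + "GATTACAG" + "CCCCC"
        assert find_exact_hits(a, b, min_n=7) == []

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # short alphabet-rich sequences produce plenty of chance 7-mers at
        # this length scale
        a, b = _seq(rng, 600), _seq(rng, 600)
        got = {
            (h.start_a, h.end_a, h.start_b, h.end_b, h.strand)
            for h in find_exact_hits(a, b)
        }
        assert got == brute_force_hits(a, b)

    def test_b_position_mapping(self):
        a = "CCCCCCC" + "GATTACAGT" + "GGGGGGG"
        b = "TTT" + "GATTACAGT" + "AAA"
        h = [x for x in find_exact_hits(a, b) if x.strand == "+"][0]
        assert b[h.b_position_of(7)] == a[7]


class TestIntersectThreeway:
    def test_planted_in_all_three(self, rng):
        core = "GATTACAG"
        za = _seq(rng, 100) + core + _seq(rng, 100)
        mb = _seq(rng, 80) + core + _seq(rng, 120)
        hc = _seq(rng, 150) + core + _seq(rng, 50)
        hits_ab = find_exact_hits(za, mb)
        shared = intersect_threeway(hits_ab, za, hc)
        assert any(core in m.sequence for m in shared)

    def test_pair_only_not_reported(self, rng):
        core = "GATTACAG"
        za = _seq(rng, 100) + core + _seq(rng, 100)
        mb = _seq(rng, 80) + core + _seq(rng, 120)
        hc = _seq(rng, 200)  # lacks the motif
        shared = intersect_threeway(find_exact_hits(za, mb), za, hc)
        assert not any(core in m.sequence for m in shared)

    def test_shared_string_occurs_in_all_inputs(self, rng):
        seqs = [_seq(rng, 400) for _ in range(3)]
        core = "TTCGCGAAC"
        za = seqs[0] + core + seqs[0][:50]
        mb = seqs[1] + revcomp(core) + seqs[1][:50]
        hc = seqs[2] + core + seqs[2][:50]
        shared = intersect_threeway(find_exact_hits(za, mb), za, hc)
        for m in shared:
            for sp, seq in (("zf", za), ("mm", mb), ("hs", hc)):
                s, e, strand = m.locations[sp]
                sub = seq[s:e].upper()
                want = m.sequence if strand == "+" else revcomp(m.sequence)
                assert sub == want

    def test_five_planted_eightmers_recovered(self, rng):
        cores = ["GATTACAGT", "TTCGCGAAC", "CCATGGATC", "AAGGTCACG", "TGACGTCAT"]
        za = mb = hc = ""
        for c in cores:
            za += _seq(rng, 60) + c
            mb += _seq(rng, 45) + c
            hc += _seq(rng, 75) + c
        shared = intersect_threeway(find_exact_hits(za, mb), za, hc)
        for c in cores:
            assert any(c in m.sequence for m in shared)


class TestChanceStatistics:
    def test_printed_joint_probability(self):
        cm = chance_statistics([(100, 100)], [int(round(100 * 100 * 2**-13.9 / 0.53))])
        # direct check of the squaring rule at the printed fraction
        assert round(0.53 * 0.53, 4) == 0.2809
        assert round(0.53 * 0.53, 2) == 0.28
        assert cm.p_joint == pytest.approx(cm.fraction**2)

    def test_ecr_pair_expectation_in_printed_range(self):
        # zebrafish 1006 bp x mouse 1031 bp at B = 13.9
        e = expected_chance_alignments(1006, 1031)
        assert e == pytest.approx(67.8, abs=0.1)
        assert 53 <= e <= 73

    def test_zero_length_zero_expectation(self):
        assert expected_chance_alignments(0, 500) == 0.0

    def test_monotonicity(self):
        e0 = expected_chance_alignments(1000, 1000)
        assert expected_chance_alignments(1001, 1000) > e0
        assert expected_chance_alignments(1000, 1001) > e0
        assert expected_chance_alignments(1000, 1000, bitscore=14.0) < e0

    def test_ratio_capped_at_one(self):
        cm = chance_statistics([(10_000, 10_000)], [1])
        assert cm.fraction == 1.0
        assert cm.p_joint == 1.0

    def test_zero_observed_warns(self, caplog):
        with caplog.at_level("WARNING"):
            cm = chance_statistics([(1000, 1000)], [0])
        assert cm.fraction == 1.0
        assert "capped" in caplog.text

    def test_expected_shared(self):
        cm = chance_statistics([(1006, 1031), (1006, 1100)], [120, 130])
        assert cm.expected_shared(29) == pytest.approx(cm.p_joint * 29)


def _near_deterministic_pfm(name, consensus, p=0.97):
    mat = np.full((4, len(consensus)), (1 - p) / 3)
    for i, c in enumerate(consensus):
        mat["ACGT".index(c), i] = p
    return Pfm(name, name, mat)


class TestMatchPfm:
    def _db(self, rng, n=8, width=8):
        return [
            _near_deterministic_pfm(f"M{i}", _seq(rng, width)) for i in range(n)
        ]

    def test_self_retrieval(self, rng):
        db = self._db(rng)
        from sef.motif_discovery import SharedMotif

        query = db[3].consensus
        motif = SharedMotif(query, {"zf": (0, len(query), "+")})
        cfg = MotifMatchConfig(null_permutations=2000, seed=5)
        out = match_pfm(motif, db, cfg)
        assert out.pfm_matches
        assert out.pfm_matches[0].motif_id == "M3"
        assert out.pfm_matches[0].e_value <= 0.1

    def test_uniform_pfm_never_beats_deterministic(self, rng):
        from sef.motif_discovery import _best_distance, _one_hot

        uniform = Pfm("U", "U", np.full((4, 8), 0.25))
        det = _near_deterministic_pfm("D", "GATTACAG")
        q = _one_hot("GATTACAG")
        d_u, _, _ = _best_distance(q, uniform.matrix)
        d_d, _, _ = _best_distance(q, det.matrix)
        assert d_d < d_u
        # uniform distance is offset-independent and analytic
        expected = np.sqrt((0.75) ** 2 + 3 * 0.25**2)
        assert d_u == pytest.approx(expected)

    def test_overlap_resolution_keeps_smaller_e(self):
        a = PfmMatch("A", "A", 0.1, 0.001, 0.01, (0, 8), "+")
        b = PfmMatch("B", "B", 0.2, 0.005, 0.05, (4, 12), "+")
        assert resolve_overlapping_matches([b, a]) == [a]
        c = PfmMatch("C", "C", 0.2, 0.005, 0.05, (8, 16), "+")
        assert resolve_overlapping_matches([c, a]) == [a, c]

    def test_short_pfm_skipped(self, rng, caplog):
        from sef.motif_discovery import SharedMotif

        db = [Pfm("tiny", "tiny", np.full((4, 3), 0.25))]
        motif = SharedMotif("GATTACAG", {"zf": (0, 8, "+")})
        with caplog.at_level("WARNING"):
            out = match_pfm(motif, db, MotifMatchConfig(null_permutations=1000))
        assert out.pfm_matches == []
        assert "skipped" in caplog.text

    def test_reproducible_under_seed(self, rng):
        from sef.motif_discovery import SharedMotif

        db = self._db(rng)
        cfg = MotifMatchConfig(null_permutations=1000, seed=9)
        q = db[0].consensus
        m1 = match_pfm(SharedMotif(q, {"zf": (0, 8, "+")}), db, cfg)
        m2 = match_pfm(SharedMotif(q, {"zf": (0, 8, "+")}), db, cfg)
        assert [(p.motif_id, p.p_value) for p in m1.pfm_matches] == [
            (p.motif_id, p.p_value) for p in m2.pfm_matches
        ]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MotifMatchConfig(e_threshold=0)
        with pytest.raises(ValueError):
            MotifMatchConfig(null_permutations=10)
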