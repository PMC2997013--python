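import numpy as np
import pytest

import _oracles as oracle
from mitekit._seq import random_seq, revcomp
from mitekit.io import GenomeSequence
from mitekit.miner import (MiteCandidate, ScanParams, cluster_families,
                           pairwise_identity, scan_candidates)

BM2_TIR = "TGAGTCGACTATTATCAAAG"  # a published 20-bp MITE TIR


def plant(background: str, pos: int, element: str, tsd: str) -> str:
    return background[:pos] + tsd + element + tsd + background[pos:]


def make_element(rng, tir: str, internal_len: int) -> str:
    return tir + random_seq(rng, internal_len, 0.6) + revcomp(tir)


class TestScan:
    def test_poly_a_has_no_candidates(self):
        assert scan_candidates(GenomeSequence("c", "A" * 5000)) == []

    def test_single_planted_element_found_exactly(self, rng):
        bg = random_seq(rng, 5000, 0.6)
        elem = make_element(rng, BM2_TIR, 238)  # 278 bp total
        genome = GenomeSequence("c", plant(bg, 2603, elem, "TA"))
        cands = scan_candidates(genome)
        ours = [c for c in cands if c.start == 2605]
        assert len(ours) == 1
        c = ours[0]
        assert (c.start, c.end) == (2605, 2883)
        assert c.tsd == "TA"
        assert c.tir_len == 20
        assert c.tir5 == BM2_TIR

    def test_element_over_600bp_not_reported(self, rng):
        bg = random_seq(rng, 4000, 0.6)
        elem = make_element(rng, BM2_TIR, 660)  # 700 bp total
        genome = GenomeSequence("c", plant(bg, 2000, elem, "TA"))
        assert all(not (abs(c.start - 2002) < 5) for c in scan_candidates(genome))

    def test_sequence_shorter_than_min_length_is_empty(self):
        assert scan_candidates(GenomeSequence("c", "ACGT" * 10)) == []

    def test_candidates_contain_no_n(self, rng):
        bg = random_seq(rng, 3000, 0.6)
        elem = make_element(rng, BM2_TIR, 238)
        broken = elem[:100] + "N" + elem[101:]
        genome = GenomeSequence("c", plant(bg, 1500, broken, "TA"))
        assert all("N" not in c.seq for c in scan_candidates(genome))

    def test_mismatch_relaxation_is_monotone(self, rng):
        bg = random_seq(rng, 4000, 0.6)
        elem = make_element(rng, BM2_TIR, 238)
        mutated = elem[:5] + "C" + elem[6:]  # one TIR mismatch
        genome = GenomeSequence("c", plant(bg, 2000, mutated, "TA"))
        strict = {(c.start, c.end)
                  for c in scan_candidates(genome, ScanParams(max_tir_mismatch=0.0))}
        relaxed = {(c.start, c.end)
                   for c in scan_candidates(genome, ScanParams(max_tir_mismatch=0.1))}
        assert strict <= relaxed

    def test_mononucleotide_tsd_run_rejected(self):
        # an (AA) TSD adjacent to a longer A-run must not be called
        rng = np.random.default_rng(404)
        bg = random_seq(rng, 2000, 0.5)
        elem = make_element(rng, "TGCGTCGACTATTATCAAGG", 160)
        seq = bg[:1000] + "AAAA" + "AA" + elem + "AA" + bg[1000:]
        cands = scan_candidates(GenomeSequence("c", seq))
        start = 1006
        assert all(not (c.start == start and c.tsd == "AA") for c in cands)


class TestOracleEquivalence:
    """The scan must reproduce an exhaustive enumeration of every admissible
    (start, end, TIR, TSD) combination after identical overlap resolution.

    An exact seed word of w bp exists inside every admissible TIR provided
    w <= ceil((tir_min - mm)/(mm + 1)); the full-sensitivity word size 5
    guarantees completeness under the default 10% mismatch allowance, and
    the default word size 8 is complete for exact TIRs.
    """

    @pytest.mark.parametrize("seed,n_planted", [(101, 2), (202, 1), (303, 0)])
    def test_scan_equals_brute_force(self, seed, n_planted):
        rng = np.random.default_rng(seed)
        bg = random_seq(rng, 1200, 0.6)
        seq = bg
        offset = 200
        for i in range(n_planted):
            elem = make_element(rng, BM2_TIR, 150 + 30 * i)
            seq = plant(seq, offset + 400 * i, elem, "ATT")
        genome = GenomeSequence("c", seq)
        got = {(c.start, c.end, c.tir_len, c.tsd)
               for c in scan_candidates(genome, ScanParams(seed_word=5))}
        expected = {(s, e, tl, tsd) for (_c, s, e, tl, tsd) in
                    oracle.resolve_overlaps(oracle.brute_force_candidates(seq))}
        assert got == expected

    def test_scan_with_mismatched_tir_matches_oracle(self):
        rng = np.random.default_rng(77)
        bg = random_seq(rng, 1000, 0.6)
        elem = make_element(rng, BM2_TIR, 200)
        elem = elem[:15] + ("C" if elem[15] != "C" else "G") + elem[16:]
        seq = plant(bg, 500, elem, "TCA")
        got = {(c.start, c.end, c.tir_len, c.tsd)
               for c in scan_candidates(GenomeSequence("c", seq),
                                        ScanParams(seed_word=5))}
        expected = {(s, e, tl, tsd) for (_c, s, e, tl, tsd) in
                    oracle.resolve_overlaps(oracle.brute_force_candidates(seq))}
        assert got == expected
        assert any(abs(s - 503) <= 2 for (s, _e, _t, _d) in got)


class TestRecovery:
    def test_all_zero_divergence_copies_recovered_exactly(self, small_bundle):
        b = small_bundle
        cands = scan_candidates(b.sequences[0])
        found = {(c.start, c.end) for c in cands}
        for t in b.truth:
            assert (t.start, t.end) in found


class TestIdentity:
    @pytest.mark.parametrize("a,b,expected", [
        ("ACGT", "ACGT", 1.0),
        ("AAAA", "AAAT", 0.75),
        ("AAAA", "TTTT", 0.0),
    ])
    def test_examples(self, a, b, expected):
        assert pairwise_identity(a, b) == pytest.approx(expected)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(20):
            a = random_seq(rng, int(rng.integers(10, 60)), 0.5)
            b = random_seq(rng, int(rng.integers(10, 60)), 0.5)
            ab = pairwise_identity(a, b)
            assert 0.0 <= ab <= 1.0
            assert ab == pytest.approx(pairwise_identity(b, a))


def _cand(seq: str, start: int = 0) -> MiteCandidate:
    return MiteCandidate("c", start, start + len(seq), seq[:8], seq[-8:],
                         "TA", seq, 0)


class TestClustering:
    def test_two_identical_candidates_do_not_form_a_family(self, rng):
        seq = random_seq(rng, 150, 0.6)
        assert cluster_families([_cand(seq, 0), _cand(seq, 500)]) == []

    def test_family_of_five_plus_outlier(self, rng):
        base = random_seq(rng, 200, 0.6)
        members = []
        for i in range(5):
            mutated = list(base)
            for j in range(i):  # up to 4 substitutions: >= 98% identity
                mutated[10 + 7 * j] = "ACGT"[("ACGT".index(mutated[10 + 7 * j]) + 1) % 4]
            members.append(_cand("".join(mutated), 1000 * i))
        outlier = _cand(random_seq(rng, 200, 0.6), 9000)
        fams = cluster_families(members + [outlier])
        assert len(fams) == 1
        assert len(fams[0].members) == 5
        # all-pairs identity oracle: every member pair exceeds the threshold
        for i in range(5):
            for j in range(i + 1, 5):
                assert pairwise_identity(members[i].seq, members[j].seq) > 0.8

    def test_three_identical_copies_form_family_with_valid_representative(self, rng):
        seq = random_seq(rng, 180, 0.6)
        cands = [_cand(seq, k * 700) for k in range(3)]
        (fam,) = cluster_families(cands)
        assert fam.representative_member in fam.members
        assert fam.representative_member.seq == seq
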