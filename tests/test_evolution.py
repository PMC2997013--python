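import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import _oracles as oracle
from mitekit.errors import (ParameterError, SaturationError,
                            UndefinedInputError)
from mitekit.evolution import (align_family, consensus, family_ages,
                               insertion_age, k2p_distance, mj_network,
                               sliding_pi, star_statistic)
from mitekit.simulate import burst_haplotypes, two_epoch_haplotypes

DNA = st.text(alphabet="ACGT", min_size=7, max_size=60)


class TestAlign:
    def test_identical_sequences_align_without_gaps(self):
        aln = align_family(["ACGTACGT"] * 3)
        assert aln.rows == ["ACGTACGT"] * 3

    def test_single_polymorphic_column(self):
        aln = align_family(["ACGTACGT", "ACGTACGT", "ACGAACGT"])
        cols = [set(c) for c in zip(*aln.rows)]
        poly = [i for i, c in enumerate(cols) if len(c) > 1]
        assert poly == [3]

    def test_deletion_appears_as_gaps_in_one_row_only(self):
        base = "ACGTACGTGCATTGCA"
        deleted = base[:6] + base[8:]
        aln = align_family([base, base, deleted], center=base)
        assert aln.rows[0] == base
        assert aln.rows[1] == base
        assert aln.rows[2].count("-") == 2
        assert len(aln.rows[2]) == len(base)


class TestConsensus:
    def test_majority_column(self):
        aln = align_family(["AAAA", "AAAA", "ACAA"])
        assert consensus(aln) == "AAAA"

    def test_tie_breaks_alphabetically(self):
        from mitekit.evolution import FamilyAlignment
        aln = FamilyAlignment("f", ["A", "A", "C", "C"], list("abcd"), "A")
        assert consensus(aln) == "A"

    def test_gap_majority_column_omitted(self):
        from mitekit.evolution import FamilyAlignment
        aln = FamilyAlignment("f", ["--A", "--A", "CAA"], list("abc"), "CAA")
        assert consensus(aln) == "A"


class TestK2P:
    def test_identical_is_zero(self):
        assert k2p_distance("GATTACA", "GATTACA") == 0.0

    def test_single_transition_closed_form(self):
        # P = 1/7, Q = 0: k = -0.5 ln(5/7)
        assert k2p_distance("GATTACA", "GACTACA") == pytest.approx(
            0.168236, abs=1e-6)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance("AAAA", "CCAA")  # Q = 0.5 -> 1 - 2Q = 0

    def test_no_shared_sites_raises(self):
        with pytest.raises(UndefinedInputError):
            k2p_distance("----", "AAAA")

    @given(DNA, DNA)
    def test_symmetric(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        try:
            d1 = k2p_distance(a, b)
        except (SaturationError, UndefinedInputError):
            return
        assert d1 == pytest.approx(k2p_distance(b, a))
        assert d1 >= 0

    def test_small_distance_limit_is_p_plus_q(self):
        # one substitution over 200 sites: k ~ P + Q within 1e-3
        a = "ACGT" * 50
        b = "ACGA" + a[4:]
        k = k2p_distance(a, b)
        assert abs(k - 1 / 200) < 1e-3


class TestAges:
    @pytest.mark.parametrize("k,years", [
        (0.0, 0.0),
        (0.0312, 1_000_000.0),
        (0.1248, 4_000_000.0),
    ])
    def test_closed_form(self, k, years):
        assert insertion_age(k) == pytest.approx(years)

    def test_bad_rate_raises(self):
        with pytest.raises(ParameterError):
            insertion_age(0.1, r=0.0)

    def test_family_ages_from_alignment(self):
        rows = ["ACGTACGTACGTACGTACGT"] * 9 + ["ACGTACGTACGTACGTACGA"]
        ages = family_ages(align_family(rows))
        assert ages[0].k == 0.0
        assert ages[-1].k > 0.0
        assert ages[-1].t_years == ages[-1].k / (2 * 1.56e-8)


class TestSlidingPi:
    def test_identical_rows_give_zero_everywhere(self):
        aln = align_family(["ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"] * 4)
        prof = sliding_pi(aln)
        assert all(pi == 0.0 for (_s, _e, pi) in prof.windows)
        assert prof.sd_pi == 0.0
        assert set(prof.classes) == {"intermediate"}

    def test_two_rows_one_mismatch_in_first_window(self):
        a = "ACGTACGTACGTACGTACGT" + "TGCATGCATGCATGCATGCA"
        b = "ACGAACGTACGTACGTACGT" + "TGCATGCATGCATGCATGCA"
        prof = sliding_pi(align_family([a, b], center=a))
        assert [round(pi, 6) for (_s, _e, pi) in prof.windows] == [0.05, 0.0]

    def test_three_rows_one_divergent_site(self):
        a = "ACGTACGTACGTACGTACGT"
        c = "ACGAACGTACGTACGTACGT"
        prof = sliding_pi(align_family([a, a, c], center=a))
        (_s, _e, pi) = prof.windows[0]
        assert pi == pytest.approx((2 / 3) / 20)

    def test_invariant_under_row_reordering(self):
        a = "ACGTACGTACGTACGTACGT"
        b = "ACGAACGTACGTACGTTCGT"
        c = "ACGTACGTACGTACGTTCGA"
        p1 = sliding_pi(align_family([a, b, c], center=a))
        p2 = sliding_pi(align_family([c, a, b], center=a))
        for (w1, w2) in zip(p1.windows, p2.windows):
            assert w1[2] == pytest.approx(w2[2])

    def test_trailing_partial_window_dropped(self):
        aln = align_family(["ACGTACGTACGTACGTACGTACGTACGTAC"] * 2)  # 30 cols
        prof = sliding_pi(aln)
        assert len(prof.windows) == 1


class TestMJNetwork:
    def test_identical_copies_condense_to_one_node(self):
        net = mj_network(["ACGT"] * 10)
        assert net.nodes == [("ACGT", 10)]
        assert net.graph.number_of_edges() == 0

    def test_burst_star_topology(self):
        h0 = "AAAAAAAAAA"
        seqs = [h0] * 10 + ["AAAAAAAAAT"] + ["AAAACAAAAA"]
        net = mj_network(seqs)
        assert sorted(net.graph.edges(data="weight")) == [
            (h0, "AAAACAAAAA", 1), (h0, "AAAAAAAAAT", 1),
        ] or net.graph.number_of_edges() == 2
        assert star_statistic(net) == 1.0

    def test_stepwise_path_topology(self):
        seqs = ["AAAA", "AAAT", "AATT"]
        net = mj_network(seqs)
        edges = {frozenset(e) for e in net.graph.edges()}
        assert edges == {frozenset(("AAAA", "AAAT")),
                         frozenset(("AAAT", "AATT"))}

    def test_multiplicities_sum_to_input_count(self):
        seqs = burst_haplotypes(n=25, seed=3)
        net = mj_network(seqs)
        assert sum(net.multiplicity.values()) == 25

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_tree_like_data_equals_mst(self, seed):
        """On tree-like haplotype sets (verified Steiner-unimprovable by the
        exhaustive oracle) the MJ network is the minimum spanning tree."""
        h = "ACGTACGTACGT"
        def mut(s, i, to):
            return s[:i] + to + s[i + 1:]
        sets = {
            1: [h, mut(h, 0, "T"), mut(mut(h, 0, "T"), 5, "A"), mut(h, 8, "G")],
            2: [h, mut(h, 1, "G"), mut(h, 6, "C")],
            3: [h, mut(h, 2, "A"), mut(mut(h, 2, "A"), 3, "C"),
                mut(mut(mut(h, 2, "A"), 3, "C"), 7, "G")],
        }
        seqs = sets[seed]
        assert len(set(seqs)) == len(seqs)
        assert not oracle.steiner_improvable(seqs)
        net = mj_network(seqs)
        mst, w = oracle.mst_edges_and_weight(seqs)
        got_w = sum(d["weight"] for _a, _b, d in net.graph.edges(data=True))
        assert net.median_vectors == []
        assert got_w == w
        assert net.graph.number_of_edges() == len(seqs) - 1

    def test_star_statistic_separates_burst_from_old_expansion(self):
        recent = mj_network(burst_haplotypes(n=40, seed=5))
        old = mj_network(two_epoch_haplotypes(n=40, seed=5))
        assert star_statistic(recent) >= 0.9
        assert star_statistic(old) <= 0.5
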