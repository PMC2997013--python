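import math

import numpy as np
import pytest

from mitekit.context import (GeneIndex, chrom_distribution_test,
                             classify_insertion, density_correlation,
                             enrichment_test, flank_bins,
                             germline_silencing_prob, simulate_null)
from mitekit.errors import ParameterError, UndefinedInputError
from mitekit.io import GeneModel, GenomeSequence
from mitekit.simulate import FamilySpec, make_genome


class _Copy:
    def __init__(self, chrom, start, end):
        self.chrom, self.start, self.end = chrom, start, end


@pytest.fixture
def gene_plus():
    return GeneModel("g1", "c", 10_000, 12_000, "+",
                     [(10_000, 10_400), (11_500, 12_000)])


class TestClassify:
    def test_midpoint_in_exon(self):
        g = GeneModel("g1", "c", 10_000, 12_000, "+")  # single exon spans gene
        ctx = classify_insertion(_Copy("c", 10_500, 10_700), [g])
        assert (ctx.category, ctx.distance) == ("exon", 0)

    def test_midpoint_in_intron(self, gene_plus):
        ctx = classify_insertion(_Copy("c", 10_500, 10_700), [gene_plus])
        assert ctx.category == "intron"

    def test_upstream_flank_is_5prime_for_plus_gene(self, gene_plus):
        ctx = classify_insertion(_Copy("c", 6_100, 6_200), [gene_plus])
        assert (ctx.category, ctx.distance) == ("5flank", 3_850)

    def test_downstream_flank_is_3prime_for_plus_gene(self, gene_plus):
        ctx = classify_insertion(_Copy("c", 12_500, 12_700), [gene_plus])
        assert ctx.category == "3flank"
        assert ctx.distance == 12_600 - 11_999

    def test_strand_flips_flank_sides(self):
        g = GeneModel("g1", "c", 10_000, 12_000, "-")
        assert classify_insertion(_Copy("c", 6_100, 6_200), [g]).category == "3flank"
        assert classify_insertion(_Copy("c", 12_500, 12_700), [g]).category == "5flank"

    def test_beyond_flank_limit_is_intergenic(self, gene_plus):
        ctx = classify_insertion(_Copy("c", 1_000, 1_200), [gene_plus])
        assert ctx.category == "intergenic"

    def test_unannotated_chromosome_is_intergenic(self, gene_plus):
        ctx = classify_insertion(_Copy("other", 500, 700), [gene_plus])
        assert ctx.category == "intergenic"

    def test_nearer_gene_wins(self):
        g1 = GeneModel("a", "c", 10_000, 11_000, "+")
        g2 = GeneModel("b", "c", 15_000, 16_000, "+")
        ctx = classify_insertion(_Copy("c", 13_950, 13_960), [g1, g2])
        assert ctx.nearest_gene == "b"  # 1045 vs 2956

    def test_truth_labels_match_classifier_on_synthetic_genome(self):
        spec = FamilySpec("F", "TGAGTCGACTATTATCAAAG", "TA", 238, 20)
        b = make_genome([spec], gene_density=40, genome_length=120_000, seed=13,
                        category_weights={"intron": 0.3, "5flank": 0.2,
                                          "3flank": 0.2, "intergenic": 0.3})
        idx = GeneIndex(b.genes)
        for t in b.truth:
            assert classify_insertion(t, idx).category == t.category_truth


class TestFlankBins:
    def test_binning_with_boundaries(self, gene_plus):
        contexts = [
            classify_insertion(_Copy("c", 6_100, 6_200), [gene_plus]),   # 3850
            classify_insertion(_Copy("c", 9_450, 9_550), [gene_plus]),   # 500
            classify_insertion(_Copy("c", 8_400, 8_600), [gene_plus]),   # 1500
        ]
        binned = flank_bins(contexts)
        assert binned["5flank"] == {"<=500": 1, "500-3000": 1, "3000-5000": 1}
        assert binned["3flank"] == {"<=500": 0, "500-3000": 0, "3000-5000": 0}

    def test_empty_contexts_all_zero(self):
        binned = flank_bins([])
        assert all(v == 0 for side in binned.values() for v in side.values())


class TestChromDistribution:
    def test_uniform_counts_give_zero_statistic(self):
        res = chrom_distribution_test([10, 10], [1e6, 1e6])
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 1

    def test_hand_computed_example(self):
        res = chrom_distribution_test([20, 10], [1e6, 1e6])
        assert res.statistic == pytest.approx(3.3333, abs=1e-3)
        assert res.p_value == pytest.approx(0.0679, abs=1e-3)

    def test_28_chromosomes_df_27(self, rng):
        counts = list(rng.integers(50, 200, size=28))
        lengths = list(rng.integers(10_000_000, 25_000_000, size=28))
        assert chrom_distribution_test(counts, lengths).df == 27

    def test_relabelling_invariance_and_count_scaling(self):
        counts = [30, 10, 20]
        lengths = [2e6, 1e6, 1e6]
        a = chrom_distribution_test(counts, lengths)
        b = chrom_distribution_test(counts[::-1], lengths[::-1])
        assert a.statistic == pytest.approx(b.statistic)
        doubled = chrom_distribution_test([2 * c for c in counts], lengths)
        assert doubled.statistic == pytest.approx(2 * a.statistic)

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ParameterError):
            chrom_distribution_test([1, 1], [0, 1e6])


class TestNullSimulation:
    def test_full_gene_cover_gives_fraction_one(self):
        genes = [GeneModel("g", "c", 0, 50_000, "+")]
        seqs = [GenomeSequence("c", "A" * 50_000)]
        null = simulate_null(seqs, genes, n=500, seed=1)
        assert null.in_gene_fraction == 1.0

    def test_same_seed_reproducible(self):
        genes = [GeneModel("g", "c", 20_000, 30_000, "+")]
        seqs = [GenomeSequence("c", "A" * 100_000)]
        n1 = simulate_null(seqs, genes, n=2_000, seed=7)
        n2 = simulate_null(seqs, genes, n=2_000, seed=7)
        assert n1.category_fractions == n2.category_fractions

    def test_constructed_cover_fraction_recovered(self):
        # gene+flank region covers 40000/100000 = 40% of midpoint mass away
        # from edge effects; binomial bound at 3 SE
        genes = [GeneModel("g", "c", 35_000, 65_000, "+")]
        seqs = [GenomeSequence("c", "A" * 100_000)]
        n = 4_000
        null = simulate_null(seqs, genes, n=n, seed=3)
        f = 0.40
        se = math.sqrt(f * (1 - f) / n)
        assert abs(null.in_gene_fraction - f) <= 3 * se

    def test_fractions_sum_to_one(self):
        genes = [GeneModel("g", "c", 20_000, 30_000, "+")]
        seqs = [GenomeSequence("c", "A" * 80_000)]
        null = simulate_null(seqs, genes, n=1_000, seed=5)
        assert sum(null.category_fractions.values()) == pytest.approx(1.0)


class TestEnrichment:
    def test_equal_proportions_give_zero(self):
        assert enrichment_test(50, 100, 50, 100).statistic == pytest.approx(0.0)
        assert enrichment_test(30, 60, 250, 500).statistic == pytest.approx(0.0)

    def test_hand_computed_two_by_two(self):
        # chi2 = n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 14.6165
        res = enrichment_test(66, 100, 39, 100)
        n, a, b, c, d = 200, 66, 34, 39, 61
        expect = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.statistic == pytest.approx(expect)
        assert res.p_value == pytest.approx(1.32e-4, rel=0.01)
        assert res.df == 1


class TestDensityCorrelation:
    def test_perfectly_proportional_densities(self, rng):
        lengths = rng.integers(5_000_000, 20_000_000, size=10)
        genes = (lengths / 1e4).astype(int)
        mites = genes * 3
        res = density_correlation(mites, genes, lengths)
        assert res.r_squared == pytest.approx(1.0)

    def test_df_is_n_minus_2(self, rng):
        lengths = rng.integers(5_000_000, 20_000_000, size=28)
        assert density_correlation(rng.integers(1, 100, 28),
                                   rng.integers(1, 100, 28), lengths).df == 26

    def test_orthogonal_densities_give_near_zero(self):
        lengths = np.full(16, 1e6)
        g = np.array([1, 2] * 8, dtype=float)
        m = np.array([1.0, 1.0, 2.0, 2.0] * 4)
        m_resid = m - np.polyval(np.polyfit(g, m, 1), g)  # residualised oracle
        res = density_correlation(m_resid - m_resid.min() + 1, g, lengths)
        assert res.r_squared < 1e-10

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedInputError):
            density_correlation([5, 5, 5], [1, 2, 3], [1e6, 1e6, 1e6])


class TestGermlineProbability:
    def test_published_inputs(self):
        assert germline_silencing_prob(8431, 10_393, 5) == pytest.approx(
            0.000241, rel=0.01)

    def test_all_expressed_gives_zero(self):
        assert germline_silencing_prob(10, 10, 3) == 0.0

    def test_none_expressed_gives_one(self):
        assert germline_silencing_prob(0, 10, 3) == 1.0

    def test_total_zero_rejected(self):
        with pytest.raises(ParameterError):
            germline_silencing_prob(0, 0, 1)
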