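import math

import numpy as np
import pytest
from scipy.stats import binom, poisson

from cnatree.bias_correction import BiasModel, IDENTITY, invert
from cnatree.clonal_model import (
    Genotype,
    LikelihoodContext,
    cn_support,
    expected_avg_copy,
    expected_folded_baf,
    folded_binom_logpmf,
    genotype_set,
    map_copy_number,
    readcount_loglik,
    segment_loglik,
    segment_loglik_phi_grid,
    snp_loglik,
)
from cnatree.segments_io import SNPLocus
from conftest import exact_mean_segment, make_segment, make_snps


# ---------------------------------------------------------------------------
# Independent linear-space oracle for the marginal segment likelihood
# ---------------------------------------------------------------------------

def oracle_segment_lik(seg, phi, theta, c_max, bias=IDENTITY):
    """Brute-force marginal likelihood in linear space using scipy pmfs
    directly: sum over the supported copy numbers and, per copy number,
    a uniform-prior average over genotypes of Poisson x folded-binomial
    products."""
    support = [0, 1, 2] if seg.corrected_ratio < theta else list(range(2, c_max + 1))
    total = 0.0
    for c in support:
        genotypes = [(c - m, m) for m in range(c + 1)] if c > 0 else [(0, 0)]
        for n_p, n_m in genotypes:
            cbar = phi * c + (1 - phi) * 2.0
            lam = invert(bias, max(cbar / 2.0 * theta, 1e-300), seg.gc) * seg.normal_reads
            term = poisson.pmf(seg.tumor_reads, lam)
            mu_t = n_m / c if c > 0 else 0.0
            m_bar = ((phi * c * mu_t if c > 0 else 0.0) + (1 - phi)) / cbar if cbar > 0 else 0.5
            p = min(m_bar, 1 - m_bar)
            for snp in seg.snps:
                b_hat = min(snp.b_count, snp.depth - snp.b_count)
                prob = binom.pmf(b_hat, snp.depth, p)
                if 2 * b_hat != snp.depth:
                    prob += binom.pmf(snp.depth - b_hat, snp.depth, p)
                term *= prob
            total += term / len(genotypes)
    return total


class TestGenotypes:
    def test_enumeration_for_c2(self):
        assert [str(g) for g in genotype_set(2)] == ["PP", "PM", "MM"]

    def test_homozygous_deletion_single_empty_genotype(self):
        (g,) = genotype_set(0)
        assert g.total == 0 and str(g) == "EMPTY"

    @pytest.mark.parametrize("c", [0, 1, 5, 15])
    def test_cardinality(self, c):
        assert len(genotype_set(c)) == c + 1


class TestExpectations:
    @pytest.mark.parametrize(
        "phi,c,expected", [(0.0, 9, 2.0), (1.0, 7, 7.0), (0.5, 5, 3.5)]
    )
    def test_expected_avg_copy(self, phi, c, expected):
        assert expected_avg_copy(phi, c) == pytest.approx(expected)

    def test_folded_baf_pure_normal_is_half(self):
        for c in (0, 1, 3, 7):
            for g in genotype_set(c):
                assert expected_folded_baf(0.0, c, g) == pytest.approx(0.5)

    def test_folded_baf_pure_tumor(self):
        assert expected_folded_baf(1.0, 4, Genotype(3, 1)) == pytest.approx(0.25)

    def test_folded_baf_mixture(self):
        assert expected_folded_baf(0.5, 4, Genotype(3, 1)) == pytest.approx(1 / 3)

    def test_folded_baf_degenerate_no_dna(self):
        assert expected_folded_baf(1.0, 0, genotype_set(0)[0]) == 0.5

    def test_folded_baf_range_property(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            c = int(rng.integers(0, 16))
            g = genotype_set(c)[int(rng.integers(0, c + 1))]
            phi = float(rng.uniform())
            val = expected_folded_baf(phi, c, g)
            assert 0.0 <= val <= 0.5
            assert expected_avg_copy(phi, c) >= 0.0


class TestSnpLoglik:
    def test_balanced_closed_form(self):
        locus = SNPLocus(chrom="c", pos=1, b_count=30, depth=60)
        expected = math.log(math.comb(60, 30) * 0.5**60)
        assert snp_loglik(locus, 0.0, 2, Genotype(1, 1)) == pytest.approx(expected)

    def test_folded_pmf_normalizes(self):
        d = 31
        for p in (0.05, 0.3, 0.5):
            total = sum(
                np.exp(folded_binom_logpmf(x, d, np.array(p))) for x in range(d // 2 + 1)
            )
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_reference_pmf_at_random_points(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            d = int(rng.integers(2, 80))
            b = int(rng.integers(0, d + 1))
            locus = SNPLocus(chrom="c", pos=1, b_count=b, depth=d)
            phi = float(rng.uniform())
            c = int(rng.integers(0, 16))
            g = genotype_set(c)[int(rng.integers(0, c + 1))]
            p = expected_folded_baf(phi, c, g)
            b_hat = min(b, d - b)
            ref = binom.pmf(b_hat, d, p)
            if 2 * b_hat != d:
                ref += binom.pmf(d - b_hat, d, p)
            if ref > 0:
                assert snp_loglik(locus, phi, c, g) == pytest.approx(
                    math.log(ref), abs=1e-10
                )


class TestReadcountLoglik:
    def ctx(self, theta=1.0):
        return LikelihoodContext(theta=theta, c_max=15)

    def test_copy_neutral_mean_equals_normal_reads(self):
        seg = make_segment(tumor=15000, normal=15000, corrected=1.0)
        ll = readcount_loglik(seg, 0.0, 2, self.ctx())
        assert ll == pytest.approx(poisson.logpmf(15000, 15000))

    def test_full_tumor_c4_doubles_mean(self):
        seg = make_segment(tumor=30000, normal=15000, corrected=2.0)
        ll = readcount_loglik(seg, 1.0, 4, self.ctx())
        assert ll == pytest.approx(poisson.logpmf(30000, 30000))

    def test_pmf_sums_to_one_at_small_mean(self):
        seg = make_segment(tumor=1, normal=10, corrected=1.0)
        ctx = LikelihoodContext(theta=1.0, c_max=15)
        lam = 0.25 * 1.0 * 10  # phi=1, C=0 -> cbar/2 = 0... use direct scan
        total = 0.0
        for k in range(0, 101):
            seg_k = make_segment(tumor=k, normal=10, corrected=1.0)
            total += np.exp(readcount_loglik(seg_k, 1.0, 1, ctx))  # lam = 5
        assert total == pytest.approx(1.0, abs=1e-10)


class TestCnSupport:
    def test_below_theta(self):
        seg = make_segment(corrected=0.8)
        assert cn_support(seg, LikelihoodContext(theta=1.0)) == (0, 1, 2)

    def test_above_theta(self):
        seg = make_segment(corrected=1.5)
        assert cn_support(seg, LikelihoodContext(theta=1.0, c_max=15)) == tuple(range(2, 16))

    def test_both_branches_contain_neutral(self):
        for ratio in (0.5, 1.0, 2.0):
            seg = make_segment(corrected=ratio)
            assert 2 in cn_support(seg, LikelihoodContext(theta=1.0))


class TestSegmentLoglik:
    def test_no_snps_reduces_to_readcount_marginal(self):
        seg = make_segment(tumor=120, normal=100, corrected=1.2)
        ctx = LikelihoodContext(theta=1.0, c_max=5)
        got = segment_loglik(seg, 0.4, ctx)
        terms = [readcount_loglik(seg, 0.4, c, ctx) for c in cn_support(seg, ctx)]
        assert got == pytest.approx(np.log(np.sum(np.exp(terms))))

    def test_matches_linear_space_oracle_on_tiny_segment(self):
        seg = make_segment(
            tumor=18, normal=15, corrected=1.2,
            snps=make_snps("chr1", [10, 20], [3, 12], [15, 18]),
        )
        ctx = LikelihoodContext(theta=1.05, c_max=6)
        for phi in (0.0, 0.3, 0.77, 1.0):
            expected = oracle_segment_lik(seg, phi, 1.05, 6)
            assert segment_loglik(seg, phi, ctx) == pytest.approx(
                math.log(expected), rel=1e-9
            )

    def test_grid_path_matches_exact_path(self):
        seg = exact_mean_segment(0.4, 5, "PMMMM", n_snps=50)
        ctx = LikelihoodContext(theta=1.0, c_max=15)
        phis = np.linspace(0.05, 0.95, 19)
        grid = segment_loglik_phi_grid(seg, phis, ctx)
        exact = np.array([segment_loglik(seg, p, ctx) for p in phis])
        assert np.max(np.abs(grid - exact)) < 1e-4

    def test_truth_beats_shifted_phi_on_average(self):
        rng = np.random.default_rng(8)
        diffs = []
        for _ in range(50):
            phi = float(rng.uniform(0.2, 0.7))
            c = int(rng.choice([1, 3, 4, 5]))
            g = genotype_set(c)[int(rng.integers(0, c + 1))]
            cbar = expected_avg_copy(phi, c)
            normal = 8000
            tumor = int(rng.poisson(cbar / 2 * normal))
            mu = expected_folded_baf(phi, c, g)
            depths = rng.poisson(30, size=60).clip(min=1)
            bs = rng.binomial(depths, mu)
            seg = make_segment(
                tumor=tumor, normal=normal, corrected=tumor / normal,
                snps=make_snps("chr1", np.arange(60) * 10 + 1, bs, depths),
            )
            ctx = LikelihoodContext(theta=1.0, c_max=15)
            shifted = phi + 0.3 if phi < 0.5 else phi - 0.3
            diffs.append(segment_loglik(seg, phi, ctx) - segment_loglik(seg, shifted, ctx))
        assert np.mean(diffs) > 0


class TestMapCopyNumber:
    def test_exact_mean_fixture_recovers_c4_pppm(self):
        seg = exact_mean_segment(1.0, 4, "PPPM")
        ctx = LikelihoodContext(theta=1.0, c_max=15)
        c, g = map_copy_number(seg, 1.0, ctx)
        assert c == 4
        assert (g.n_p, g.n_m) == (3, 1)  # mirror tie broken to fewer M copies

    def test_simulated_homozygous_deletion(self, scenario_run):
        truth = scenario_run["truth"]
        seg = scenario_run["segset"].by_id(truth.scna_segment_ids["scna0"])
        c, _ = map_copy_number(seg, 0.95, scenario_run["ctx"])
        assert c == 0

    def test_argmax_matches_brute_force_scan(self):
        seg = make_segment(
            tumor=130, normal=100, corrected=1.3,
            snps=make_snps("chr1", [5, 15, 25], [4, 10, 2], [12, 20, 9]),
        )
        ctx = LikelihoodContext(theta=1.0, c_max=8)
        phi = 0.6
        best, best_val = None, -np.inf
        for c in cn_support(seg, ctx):
            for g in genotype_set(c):
                val = readcount_loglik(seg, phi, c, ctx) - np.log(len(genotype_set(c)))
                for snp in seg.snps:
                    val += snp_loglik(snp, phi, c, g)
                if val > best_val + 1e-12:
                    best, best_val = (c, (g.n_p, g.n_m)), val
        c_map, g_map = map_copy_number(seg, phi, ctx)
        assert (c_map, (g_map.n_p, g_map.n_m)) == best
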