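"""Tests of diversity, rarefaction, LD and differentiation statistics."""

from itertools import combinations, permutations

import numpy as np
import pytest

from landgen.datatypes import AnalysisError, ConfigurationError, DistanceMatrix
from landgen.popgen import (
    diversity_stats,
    fst_meirmans,
    gst_hedrick,
    hierarchical_f,
    ld_r2,
    matrix_correlation,
    pairwise_fst_nei,
    rarefied_allelic_richness,
    richness_permutation_test,
)
from tests.conftest import build_gm
from tests.test_synthetic import _wc_theta_multilocus


class TestDiversity:
    def test_all_heterozygotes(self):
        gm = build_gm([[1]] * 6, ["A"] * 6)
        d = diversity_stats(gm, "site_id")
        assert d["H_O"].iloc[0] == 1.0
        assert d["F_IS"].iloc[0] < 0

    def test_monomorphic_convention(self):
        gm = build_gm([[0]] * 5, ["A"] * 5)
        d = diversity_stats(gm, "site_id")
        assert d["H_O"].iloc[0] == 0.0
        assert d["H_E"].iloc[0] == 0.0
        assert d["F_IS"].iloc[0] == 0.0

    def test_hand_count_oracle(self):
        """5 diploids (0,0,1,1,2): p=0.4, He = 2pq * 2n/(2n-1), Ho=0.4."""
        gm = build_gm([[0], [0], [1], [1], [2]], ["A"] * 5)
        d = diversity_stats(gm, "site_id")
        p = 4 / 10
        he = 2 * p * (1 - p) * 10 / 9
        assert d["H_O"].iloc[0] == pytest.approx(0.4, abs=1e-12)
        assert d["H_E"].iloc[0] == pytest.approx(he, abs=1e-12)
        assert d["F_IS"].iloc[0] == pytest.approx(1 - 0.4 / he, abs=1e-12)

    def test_small_group_error_names_group(self):
        gm = build_gm([[0], [1], [2]], ["A", "A", "B"])
        with pytest.raises(AnalysisError, match="B"):
            diversity_stats(gm, "site_id")


class TestRarefaction:
    def test_full_sample_equals_observed_count(self):
        gm = build_gm([[0], [0], [0], [0], [1]], ["A"] * 5)
        ar, _, _ = rarefied_allelic_richness(gm, "site_id", g=10)
        assert ar.iloc[0] == pytest.approx(2.0, abs=1e-12)

    def test_monomorphic_is_one(self):
        gm = build_gm([[2]] * 5, ["A"] * 5)
        for g in (2, 4, 8):
            ar, _, _ = rarefied_allelic_richness(gm, "site_id", g=g)
            assert ar.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_enumeration_oracle(self):
        """N=10 copies (9 ref, 1 alt), g=2: exhaustive subsample enumeration."""
        gm = build_gm([[0], [0], [0], [0], [1]], ["A"] * 5)
        copies = [0] * 9 + [1]
        vals = [len(set(sub)) for sub in combinations(copies, 2)]
        expected = np.mean(vals) + 0  # mean allele count over all C(10,2) draws
        # mean subsample allele count == sum_i P(allele i present)
        ar, _, _ = rarefied_allelic_richness(gm, "site_id", g=2)
        assert ar.iloc[0] == pytest.approx(expected, abs=1e-12)
        assert ar.iloc[0] == pytest.approx(1.2, abs=1e-9)

    def test_g_below_two_rejected(self):
        gm = build_gm([[0], [1]], ["A", "A"])
        with pytest.raises(ConfigurationError):
            rarefied_allelic_richness(gm, "site_id", g=1)


class TestRichnessPermutation:
    def _two_group_gm(self, rng, shift=0.0, n_loci=30):
        a = rng.binomial(2, 0.5, size=(6, n_loci))
        b = rng.binomial(2, np.clip(0.5 + shift, 0, 1), size=(6, n_loci))
        return build_gm(
            np.vstack([a, b]), ["A"] * 6 + ["B"] * 6,
            ecotopes=["domestic"] * 6 + ["wild"] * 6,
        )

    def test_identical_groups_p_one(self):
        geno = np.tile([[0], [1], [2], [1]], (2, 1))
        gm = build_gm(geno, ["A"] * 4 + ["B"] * 4)
        res = richness_permutation_test(gm, "A", "B", grouping="site_id",
                                        n_perm=200, seed=1)
        assert res["p"] == 1.0

    def test_exhaustive_small_case(self):
        """3 vs 3 per-locus values: MC p agrees with enumerating all 6!/(3!3!)
        relabellings of the pooled values."""
        rng = np.random.default_rng(4)
        gm = self._two_group_gm(rng, shift=0.25, n_loci=3)
        res = richness_permutation_test(gm, "A", "B", grouping="site_id",
                                        n_perm=4999, seed=2)
        _, per_locus, _ = rarefied_allelic_richness(gm, "site_id")
        va = per_locus.loc["A"].dropna().to_numpy()
        vb = per_locus.loc["B"].dropna().to_numpy()
        pooled = np.concatenate([va, vb])
        obs = abs(va.mean() - vb.mean())
        hits = total = 0
        for comb in combinations(range(len(pooled)), len(va)):
            mask = np.zeros(len(pooled), bool)
            mask[list(comb)] = True
            t = abs(pooled[mask].mean() - pooled[~mask].mean())
            hits += int(t >= obs - 1e-15)
            total += 1
        p_exact = hits / total
        assert abs(res["p"] - p_exact) < 0.05


class TestLD:
    def test_duplicated_locus_r2_one(self):
        rng = np.random.default_rng(0)
        col = rng.binomial(2, 0.4, size=20)
        gm = build_gm(np.column_stack([col, col]), ["A"] * 20)
        out = ld_r2(gm)
        assert out["r2_matrix"][0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_hand_pearson_oracle(self):
        g = np.array([[0, 2], [1, 1], [2, 0], [2, 2]], dtype=np.int8)
        gm = build_gm(g, ["A"] * 4)
        r = np.corrcoef(g[:, 0], g[:, 1])[0, 1]
        out = ld_r2(gm)
        assert out["r2_matrix"][0, 1] == pytest.approx(r**2, abs=1e-12)

    def test_independent_loci_mean_r2(self):
        """For independent loci, E[r^2] ~ 1/n."""
        rng = np.random.default_rng(8)
        n = 1000
        gm = build_gm(rng.binomial(2, 0.5, size=(n, 40)), ["A"] * n)
        out = ld_r2(gm)
        iu = np.triu_indices(40, 1)
        mean_r2 = np.nanmean(out["r2_matrix"][iu])
        assert abs(mean_r2 - 1.0 / n) < 3.0 / n

    def test_monomorphic_pair_excluded(self):
        g = np.array([[0, 0], [0, 1], [0, 2], [0, 1]], dtype=np.int8)
        gm = build_gm(g, ["A"] * 4)
        out = ld_r2(gm)
        assert out["n_excluded"] == 1


def _nei_fst_oracle(counts_a, counts_b):
    """Hand transcription of Nei (1973) F_ST for two groups, one locus.

    counts = (n_diploids, alt_copies, n_het); Hs uses unbiased gene
    diversity, Ht the unweighted mean frequency.
    """
    (na, alta, _), (nb, altb, _) = counts_a, counts_b
    pa, pb = alta / (2 * na), altb / (2 * nb)
    hs = 0.5 * (
        2 * pa * (1 - pa) * 2 * na / (2 * na - 1)
        + 2 * pb * (1 - pb) * 2 * nb / (2 * nb - 1)
    )
    pbar = (pa + pb) / 2
    ht = 2 * pbar * (1 - pbar)
    return (ht - hs) / ht


def _corrected_oracle(counts_a, counts_b):
    """Hand transcription of the Nei & Chesser (1983) estimators and the
    Hedrick/Meirmans corrections for two groups at one locus.

    Returns (G''st, F'st)."""
    (na, alta, ha), (nb, altb, hb) = counts_a, counts_b
    k = 2
    pa, pb = alta / (2 * na), altb / (2 * nb)
    n_harm = k / (1 / na + 1 / nb)
    ho = (ha / na + hb / nb) / 2
    hs0 = (2 * pa * (1 - pa) + 2 * pb * (1 - pb)) / 2
    hs = n_harm / (n_harm - 1) * (hs0 - ho / (2 * n_harm))
    pbar = (pa + pb) / 2
    ht = 2 * pbar * (1 - pbar) + hs / (n_harm * k) - ho / (2 * n_harm * k)
    g2 = k * (ht - hs) / ((k * ht - hs) * (1 - hs))
    gst = (ht - hs) / ht
    ht_max = (1 - (pa**2 + (1 - pa) ** 2 + pb**2 + (1 - pb) ** 2) / k**2) \
        + hs / (n_harm * k) - ho / (2 * n_harm * k)
    fprime = gst / ((ht_max - hs) / ht_max)
    return g2, fprime


def _two_pop_gm():
    """p1=0.8 (6 hom-alt, 4 het), p2=0.3 (6 het, 4 hom-ref), n=10 each."""
    a = [[2]] * 6 + [[1]] * 4
    b = [[1]] * 6 + [[0]] * 4
    return build_gm(a + b, ["A"] * 10 + ["B"] * 10)


class TestDifferentiation:
    def test_alternate_fixation_is_one(self):
        gm = build_gm([[0]] * 5 + [[2]] * 5, ["A"] * 5 + ["B"] * 5)
        assert gst_hedrick(gm, "site_id").values[0, 1] == pytest.approx(1.0, abs=1e-10)
        assert fst_meirmans(gm, "site_id").values[0, 1] == pytest.approx(1.0, abs=1e-10)
        fst, p, _ = pairwise_fst_nei(gm, "site_id", n_perm=199, seed=0)
        assert fst.values[0, 1] == pytest.approx(1.0, abs=1e-10)
        assert p.values[0, 1] <= 0.05

    def test_identical_frequencies_zero(self):
        block = [[0], [1], [1], [2]]
        gm = build_gm(block + block, ["A"] * 4 + ["B"] * 4)
        assert gst_hedrick(gm, "site_id").values[0, 1] <= 1e-10
        assert fst_meirmans(gm, "site_id").values[0, 1] <= 1e-10

    def test_hand_formula_oracle_two_pop(self):
        gm = _two_pop_gm()
        counts_a = (10, 16, 4)
        counts_b = (10, 6, 6)
        g2_exp, fp_exp = _corrected_oracle(counts_a, counts_b)
        fst_exp = _nei_fst_oracle(counts_a, counts_b)
        assert gst_hedrick(gm, "site_id").values[0, 1] == pytest.approx(g2_exp, abs=1e-10)
        assert fst_meirmans(gm, "site_id").values[0, 1] == pytest.approx(fp_exp, abs=1e-10)
        fst, _, _ = pairwise_fst_nei(gm, "site_id", n_perm=0, test_pairs=[])
        assert fst.values[0, 1] == pytest.approx(fst_exp, abs=1e-10)

    def test_gpp_dominates_nei_fst(self):
        """G''_ST >= Nei F_ST pair-by-pair whenever H_S > 0."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            p = rng.uniform(0.1, 0.9, size=(3, 20))
            geno = np.concatenate(
                [rng.binomial(2, p[k][None, :].repeat(8, 0)) for k in range(3)]
            )
            gm = build_gm(geno, np.repeat(["A", "B", "C"], 8))
            g2 = gst_hedrick(gm, "site_id").values
            fst = pairwise_fst_nei(gm, "site_id", n_perm=0, test_pairs=[])[0].values
            iu = np.triu_indices(3, 1)
            assert (g2[iu] >= fst[iu] - 1e-9).all()

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        geno = rng.integers(0, 3, size=(16, 25))
        sites = np.repeat(["A", "B"], 8)
        gm = build_gm(geno, sites)
        perm = rng.permutation(16)
        gm_p = build_gm(geno[perm], sites[perm])
        a = gst_hedrick(gm, "site_id").values
        b = gst_hedrick(gm_p, "site_id").values
        assert np.allclose(a, b, atol=1e-12)

    def test_null_pvalues_not_anticonservative(self):
        """Permutation p-values under a panmictic null are stochastically >=
        uniform."""
        rng = np.random.default_rng(23)
        ps = []
        for _ in range(60):
            geno = rng.binomial(2, rng.uniform(0.2, 0.8, 20)[None, :].repeat(12, 0))
            gm = build_gm(geno, ["A"] * 6 + ["B"] * 6)
            _, p, _ = pairwise_fst_nei(gm, "site_id", n_perm=49,
                                       seed=int(rng.integers(2**31)))
            ps.append(p.values[0, 1])
        ps = np.asarray(ps)
        for level in (0.05, 0.1, 0.25):
            emp = (ps <= level).mean()
            se = np.sqrt(level * (1 - level) / len(ps))
            assert emp <= level + 3 * se + 0.02


class TestMatrixCorrelation:
    def _dm(self, vals):
        n = vals.shape[0]
        return DistanceMatrix([f"g{i}" for i in range(n)], vals)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 5, (6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        res = matrix_correlation(self._dm(a), self._dm(2 * a + 1), n_perm=99)
        assert res["r2"] == pytest.approx(1.0, abs=1e-12)

    def test_negation_gives_minus_one(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(1, 5, (5, 5))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        res = matrix_correlation(self._dm(a), self._dm(-a), n_perm=99)
        assert res["r"] == pytest.approx(-1.0, abs=1e-12)

    def test_constant_matrix_undefined(self):
        c = np.ones((4, 4)) - np.eye(4)
        res = matrix_correlation(self._dm(c), self._dm(c * 2), n_perm=9)
        assert np.isnan(res["r"])

    def test_independent_matrices_near_zero(self):
        rng = np.random.default_rng(7)
        rs = []
        for _ in range(20):
            a = rng.uniform(0, 1, (10, 10)); a = (a + a.T) / 2; np.fill_diagonal(a, 0)
            b = rng.uniform(0, 1, (10, 10)); b = (b + b.T) / 2; np.fill_diagonal(b, 0)
            rs.append(matrix_correlation(self._dm(a), self._dm(b), n_perm=9)["r"])
        assert abs(np.mean(rs)) < 0.15


class TestHierarchicalF:
    def test_two_level_matches_wc_theta(self):
        """Collapsed (sites-only) hierarchy equals brute-force WC theta."""
        rng = np.random.default_rng(17)
        geno = rng.integers(0, 3, size=(24, 40))
        pops = np.repeat(["A", "B", "C"], 8)
        gm = build_gm(geno, pops)
        res = hierarchical_f(gm, ["site_id"], n_perm=0, n_boot=5, seed=0)
        assert res.f_stats["site_id/total"] == pytest.approx(
            _wc_theta_multilocus(geno, pops), abs=1e-10
        )

    def test_random_ecotope_f_near_zero(self):
        """Ecotope labels shuffled within sites: F_ecotope/site ~ 0."""
        rng = np.random.default_rng(31)
        vals = []
        for rep in range(5):
            p = rng.uniform(0.2, 0.8, size=(4, 60))
            geno = np.concatenate(
                [rng.binomial(2, p[k][None, :].repeat(10, 0)) for k in range(4)]
            )
            sites = np.repeat(["A", "B", "C", "D"], 10)
            ecos = np.array(["domestic", "wild"] * 20)
            gm = build_gm(geno, sites, ecotopes=list(ecos))
            res = hierarchical_f(gm, ["site_id", "ecotope"], n_perm=0, n_boot=5, seed=rep)
            vals.append(res.f_stats["ecotope/site_id"])
        assert abs(np.mean(vals)) < 0.01

    def test_panmictic_p_uniformish(self):
        rng = np.random.default_rng(13)
        geno = rng.binomial(2, 0.5, size=(30, 30))
        gm = build_gm(geno, np.repeat(["A", "B", "C"], 10))
        res = hierarchical_f(gm, ["site_id"], n_perm=99, n_boot=10, seed=3)
        assert res.p["site_id/total"] > 0.01

    def test_single_group_level_nan(self):
        rng = np.random.default_rng(1)
        geno = rng.integers(0, 3, size=(10, 10))
        gm = build_gm(geno, ["A"] * 10)
        res = hierarchical_f(gm, ["site_id"], n_perm=0, n_boot=2, seed=0)
        assert np.isnan(res.f_stats["site_id/total"]) or res.f_stats["site_id/total"] == 0.0
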