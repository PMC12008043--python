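import numpy as np
import pandas as pd
import pytest
from scipy import stats

from urbanpopgen import diversity as div
from conftest import make_matrix


def brute_force_pi(haplotypes, total_sites):
    """Mean pairwise difference per site over all haplotype pairs."""
    h = np.asarray(haplotypes)
    n = h.shape[0]
    diffs = [np.sum(h[i] != h[j]) for i in range(n) for j in range(i + 1, n)]
    return np.mean(diffs) / total_sites


def independent_tajimas_d(s, pi_sum, n):
    """Closed-form Tajima's D written independently of the module."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (pi_sum - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


class TestNucleotideDiversity:
    def test_monomorphic_unit_is_zero(self):
        g = make_matrix(np.zeros((4, 6)), locus_len=50)
        assert div.nucleotide_diversity(g) == 0.0

    def test_matches_brute_force_pairwise(self):
        # 4 haplotypes -> 2 diploids, 100 sites in one locus
        rng = np.random.default_rng(7)
        hap = rng.binomial(1, 0.3, size=(4, 12))
        hap = hap[:, hap.sum(axis=0) > 0]           # keep variant columns
        dip = hap[::2] + hap[1::2]
        loci = ["LOC"] * dip.shape[1]
        g = make_matrix(dip, loci=loci, locus_len=100)
        expected = brute_force_pi(hap, 100)
        assert div.nucleotide_diversity(g) == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_order_and_allele_relabeling(self):
        rng = np.random.default_rng(8)
        geno = rng.integers(0, 3, size=(10, 30)).astype(np.int8)
        g = make_matrix(geno)
        perm = rng.permutation(10)
        g_perm = make_matrix(geno[perm])
        g_flip = make_matrix(2 - geno)
        assert div.nucleotide_diversity(g) == pytest.approx(
            div.nucleotide_diversity(g_perm))
        assert div.nucleotide_diversity(g) == pytest.approx(
            div.nucleotide_diversity(g_flip))
        assert div.wattersons_theta(g) == pytest.approx(
            div.wattersons_theta(g_flip))


class TestWattersonsTheta:
    def test_no_segregating_sites(self):
        g = make_matrix(np.full((5, 4), 2), locus_len=50)
        assert div.wattersons_theta(g) == 0.0

    def test_direct_formula(self):
        # 5 segregating SNPs among 5 diploids (10 copies), 100 total sites
        geno = np.zeros((5, 5), dtype=np.int8)
        geno[0, :] = 1
        g = make_matrix(geno, loci=["A"] * 5, locus_len=100)
        a1 = sum(1.0 / i for i in range(1, 10))
        assert div.wattersons_theta(g) == pytest.approx(5 / (a1 * 100))


class TestHeterozygosity:
    def test_excess_heterozygosity_is_negative_fis(self):
        g = make_matrix(np.ones((6, 10)))
        h_obs, h_exp, fis = div.heterozygosity_fis(g)
        assert h_obs == 1.0
        assert fis < 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        geno = rng.integers(-1, 3, size=(10, 50)).astype(np.int8)
        g = make_matrix(geno)
        h_obs, h_exp, fis = div.heterozygosity_fis(g)
        obs, exp, f = [], [], []
        for j in range(50):
            calls = geno[:, j][geno[:, j] >= 0]
            if len(calls) == 0:
                continue
            n = 2 * len(calls)
            p = calls.sum() / n
            he = 2 * p * (1 - p) * n / (n - 1)
            if he <= 0:
                continue
            ho = np.mean(calls == 1)
            obs.append(ho), exp.append(he), f.append(1 - ho / he)
        assert h_obs == pytest.approx(np.mean(obs))
        assert h_exp == pytest.approx(np.mean(exp))
        assert fis == pytest.approx(np.mean(f))


class TestTajimasD:
    def test_textbook_case_to_three_decimals(self):
        ours = div.tajimas_d(16, 3.888, 10)
        theirs = independent_tajimas_d(16, 3.888, 10)
        assert ours == pytest.approx(theirs, abs=1e-3)

    def test_windows_tile_from_position_one(self):
        rng = np.random.default_rng(10)
        geno = rng.integers(0, 3, size=(10, 40)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 350_000), 40, replace=False))
        g = make_matrix(geno, pos=pos)
        tab = div.tajimas_d_windows(g, window_bp=100_000)
        assert tab["start"].iloc[0] == 1
        assert (tab["end"] - tab["start"] == 100_000).all()
        assert not (tab.loc[tab["S"] < 2, "defined"]).any()

    def test_neutral_simulation_centers_near_zero(self, small_panmictic):
        g, _ = small_panmictic
        tab = div.tajimas_d_windows(g)
        d = tab.loc[tab.defined, "D"]
        assert abs(d.mean()) < 0.4  # single replicate; acceptance tightens this


class TestDTests:
    def _table(self, d):
        return pd.DataFrame({"chrom": "1", "start": 1, "end": 2,
                             "S": 5, "D": d, "defined": np.isfinite(d)})

    def test_identical_tables_give_t0_p1(self):
        rng = np.random.default_rng(11)
        tab = self._table(rng.normal(size=50))
        res = div.d_tests(tab, tab)
        two = res[res.test == "two_sample"].iloc[0]
        assert two["t"] == 0.0 and two["p"] == 1.0

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(12)
        a = self._table(rng.normal(size=200))
        b = self._table(rng.normal(size=200) - 0.5)
        res = div.d_tests(a, b)
        assert res[res.test == "two_sample"]["p"].iloc[0] < 1e-3


class TestUrbanizationModel:
    def _site_table(self, slope, n=40, seed=13):
        rng = np.random.default_rng(seed)
        dist = rng.uniform(0, 60, n)
        nind = rng.integers(2, 6, n)
        pi = 0.001 + slope * dist + 0.0001 * rng.normal(size=n)
        return pd.DataFrame({"pi": pi, "dist_km": dist, "n_individuals": nind})

    def test_matches_normal_equations(self):
        tab = self._site_table(2e-6)
        res = div.urbanization_model(tab, "pi", "dist_km")
        x = np.column_stack([np.ones(len(tab)), tab.dist_km, tab.n_individuals])
        beta = np.linalg.solve(x.T @ x, x.T @ tab.pi.values)
        assert res.coefficients["dist_km"] == pytest.approx(beta[1], abs=1e-8)
        assert res.coefficients["const"] == pytest.approx(beta[0], abs=1e-8)

    def test_null_slope_not_significant(self):
        pvals = [div.urbanization_model(self._site_table(0.0, seed=s),
                                        "pi", "dist_km").p for s in range(40)]
        # roughly uniform: no pile-up at small values
        assert np.mean(np.array(pvals) < 0.05) < 0.25

    def test_single_individual_sites_excluded(self):
        tab = self._site_table(2e-6)
        tab.loc[:30, "n_individuals"] = 1
        res = div.urbanization_model(tab, "pi", "dist_km")
        assert res.n_sites == len(tab) - 31
        with pytest.raises(ValueError):
            div.urbanization_model(tab.iloc[:33], "pi", "dist_km")
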