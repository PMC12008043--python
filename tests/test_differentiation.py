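import numpy as np
import pytest

from urbanpopgen import differentiation as diff, simulate as sim
from conftest import make_matrix


class TestHudsonFst:
    def test_hand_evaluated_single_snp(self):
        p1, p2, n1, n2 = 0.5, 0.1, 10.0, 10.0
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        assert diff.hudson_fst_pair([p1], [p2], [n1], [n2]) == pytest.approx(num / den)

    def test_identical_frequencies_nonpositive(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.95, 200)
        assert diff.hudson_fst_pair(p, p, np.full(200, 20.0), np.full(200, 20.0)) <= 0

    def test_ratio_of_averages_matches_explicit_sum(self):
        rng = np.random.default_rng(2)
        p1 = rng.uniform(0, 1, 100)
        p2 = rng.uniform(0, 1, 100)
        n1 = rng.integers(4, 30, 100).astype(float)
        n2 = rng.integers(4, 30, 100).astype(float)
        total_num = total_den = 0.0
        for a, b, x, y in zip(p1, p2, n1, n2):
            total_num += (a - b) ** 2 - a * (1 - a) / (x - 1) - b * (1 - b) / (y - 1)
            total_den += a * (1 - b) + b * (1 - a)
        assert diff.hudson_fst_pair(p1, p2, n1, n2) == pytest.approx(
            total_num / total_den, rel=1e-12)

    def test_zero_denominator_flagged_nan(self):
        assert np.isnan(diff.hudson_fst_pair([0.0], [0.0], [10.0], [10.0]))

    def test_matrix_excludes_single_individual_sites(self):
        rng = np.random.default_rng(3)
        geno = rng.integers(0, 3, size=(7, 50)).astype(np.int8)
        g = make_matrix(geno)
        sites = ["s1"] * 3 + ["s2"] * 3 + ["s3"]
        res = diff.fst_matrix(g, sites)
        assert res.excluded_sites == ["s3"]
        assert list(res.matrix.columns) == ["s1", "s2"]
        assert res.matrix.loc["s1", "s2"] == res.matrix.loc["s2", "s1"]


class TestAmova:
    def _random(self, seed=4, n_groups=2, sites_per_group=4, per_site=4):
        rng = np.random.default_rng(seed)
        n = n_groups * sites_per_group * per_site
        x = rng.normal(size=(n, 30))
        sites = np.repeat(np.arange(n_groups * sites_per_group).astype(str), per_site)
        groups = np.repeat(np.array(["g0", "g1"])[:n_groups],
                           sites_per_group * per_site)
        return x, sites, groups

    def test_identical_individuals_zero_components(self):
        x = np.ones((12, 5))
        sites = np.repeat(["a", "b", "c"], 4)
        groups = np.repeat(["g0", "g0", "g1"], 4)
        res = diff.amova(x, sites, groups, n_perm=9, seed=0)
        assert np.allclose(res.table["SS"], 0.0)
        assert res.table["percent"].isna().all()

    def test_ss_additivity(self):
        x, sites, groups = self._random()
        res = diff.amova(x, sites, groups, n_perm=9, seed=1)
        assert res.table["SS"].sum() == pytest.approx(
            res.components["SS_total"], rel=1e-10)

    def test_components_match_explicit_anova(self):
        """Distance decomposition equals the direct frequency-vector ANOVA."""
        x, sites, groups = self._random(seed=5)
        res = diff.amova(x, sites, groups, n_perm=0, seed=1)
        # explicit sums of squared deviations around means
        grand = x.mean(axis=0)
        ss_total = np.sum((x - grand) ** 2)
        ss_ws = 0.0
        for s in np.unique(sites):
            sub = x[sites == s]
            ss_ws += np.sum((sub - sub.mean(axis=0)) ** 2)
        ss_wg = 0.0
        for gr in np.unique(groups):
            sub = x[groups == gr]
            ss_wg += np.sum((sub - sub.mean(axis=0)) ** 2)
        assert res.components["SS_total"] == pytest.approx(ss_total, abs=1e-8)
        tab = res.table.set_index("component")
        assert tab.loc["within_sites", "SS"] == pytest.approx(ss_ws, abs=1e-8)
        assert tab.loc["among_groups", "SS"] == pytest.approx(
            ss_total - ss_wg, abs=1e-8)

    def test_two_demes_put_variance_among_groups(self):
        scn = sim.SimulationScenario(model="two_deme", epochs=[(0.0, 65000.0)],
                                     n_demes=2, scaled_migration=1.0,
                                     n_individuals=32, n_loci=600, seed=6)
        g, labels, _ = sim.simulate_two_habitat(scn)
        sites = [f"{lab}{i % 8}" for i, lab in enumerate(labels)]
        res = diff.amova(g, sites, list(labels), n_perm=199, seed=7)
        tab = res.table.set_index("component")
        assert tab.loc["among_groups", "percent"] > 50
        assert tab.loc["among_groups", "p"] <= 0.01


class TestPermanova:
    def test_label_swap_invariance(self):
        rng = np.random.default_rng(8)
        d = diff.euclidean_distance_matrix(rng.normal(size=(16, 10)))
        labels = ["a"] * 8 + ["b"] * 8
        swapped = ["b"] * 8 + ["a"] * 8
        f1, _ = diff.permanova(d, labels, n_perm=9, seed=1)
        f2, _ = diff.permanova(d, swapped, n_perm=9, seed=1)
        assert f1 == pytest.approx(f2)

    def test_separated_clouds_minimal_p(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(30, 5))
        x[15:] += 10.0  # 10 SD separation
        d = diff.euclidean_distance_matrix(x)
        labels = ["a"] * 15 + ["b"] * 15
        f, p = diff.permanova(d, labels, n_perm=199, seed=2)
        assert p == pytest.approx(1 / 200)

    def test_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova, DistanceMatrix

        rng = np.random.default_rng(10)
        d = diff.euclidean_distance_matrix(rng.normal(size=(20, 8)))
        labels = ["a"] * 10 + ["b"] * 10
        f, _ = diff.permanova(d, labels, n_perm=9, seed=3)
        res = sk_permanova(DistanceMatrix(d), labels, permutations=9)
        assert f == pytest.approx(res["test statistic"], rel=1e-10)


class TestPermdisp:
    def test_single_group_rejected(self):
        d = diff.euclidean_distance_matrix(np.random.default_rng(0).normal(size=(6, 3)))
        with pytest.raises(ValueError):
            diff.permdisp(d, ["a"] * 6, n_perm=9)

    def test_doubled_dispersion_detected(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=(60, 5))
        b = 3.0 * rng.normal(size=(60, 5))
        d = diff.euclidean_distance_matrix(np.vstack([a, b]))
        labels = ["a"] * 60 + ["b"] * 60
        f, p = diff.permdisp(d, labels, n_perm=199, seed=4)
        assert p < 0.01

    def test_matches_scikit_bio_centroid_statistic(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permdisp as sk_permdisp, DistanceMatrix

        rng = np.random.default_rng(12)
        d = diff.euclidean_distance_matrix(rng.normal(size=(24, 6)))
        labels = ["a"] * 12 + ["b"] * 12
        f, _ = diff.permdisp(d, labels, n_perm=9, seed=5, center="centroid")
        res = sk_permdisp(DistanceMatrix(d), labels, permutations=9, test="centroid")
        assert f == pytest.approx(res["test statistic"], rel=1e-6)
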