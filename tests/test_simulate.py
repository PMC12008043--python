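import numpy as np
import pytest
from scipy import stats

from urbanpopgen import geno_io, simulate as sim, urban_class
from urbanpopgen.diversity import harmonic


class TestCoalescent:
    def test_same_seed_byte_identical_vcf(self, tmp_path):
        for tag in ("a", "b"):
            scn = sim.scenario_preset("null_panmixia", n_individuals=10,
                                      n_loci=150, seed=42)
            g, _ = sim.simulate_coalescent(scn)
            geno_io.write_vcf(g, tmp_path / f"{tag}.vcf")
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()

    def test_watterson_closed_form(self):
        ne, n_ind, n_loci, L = 65000.0, 20, 2000, 74
        scn = sim.scenario_preset("null_panmixia", n_individuals=n_ind,
                                  n_loci=n_loci, seed=1)
        g, _ = sim.simulate_coalescent(scn)
        theta_site = 4 * ne * scn.mu
        expected_s = theta_site * L * harmonic(2 * n_ind) * n_loci
        # Poisson-scale fluctuation around the coalescent expectation
        assert abs(g.n_snps - expected_s) < 4 * np.sqrt(expected_s) + 0.05 * expected_s

    def test_pairwise_tmrca_for_two_copies(self):
        ne = 20000.0
        scn = sim.scenario_preset("null_panmixia", n_individuals=1, n_loci=4000,
                                  seed=2)
        scn.epochs = [(0.0, ne)]
        g, _ = sim.simulate_coalescent(scn)
        # E[pi per site] = 2 mu TMRCA = 4 Ne mu for n=2 copies; per-locus S
        # is overdispersed (Var ~ m + m^2 from the exponential TMRCA), so
        # the 4000-locus mean carries ~5% relative SD: test at 4 SD
        het = np.mean(np.sum(g.genotypes == 1, axis=1)) / g.total_sites
        assert het == pytest.approx(4 * ne * scn.mu, rel=0.2)

    def test_mutation_engine_matches_msprime(self):
        """In-package mutation placement reproduces msprime's binary
        infinite-sites model in distribution.

        Per-locus summaries (segregating sites, singleton count, pairwise
        diversity) are compared between engines as means with the sampling
        SD estimated from the per-locus values themselves; per-bin SFS
        comparisons would be invalid here because SNPs within a locus
        share one genealogy and are strongly overdispersed.
        """
        import msprime

        n_loci = 4000
        scn = sim.scenario_preset("null_panmixia", n_individuals=10,
                                  n_loci=n_loci, seed=3)
        g, _ = sim.simulate_coalescent(scn)

        def per_locus_stats(counts_by_locus):
            out = []
            for ac_list in counts_by_locus:
                ac = np.asarray(ac_list)
                s = len(ac)
                singletons = int(np.sum((ac == 1) | (ac == 19)))
                pi = float(np.sum(2 * ac * (20 - ac) / (20 * 19)))
                out.append((s, singletons, pi))
            return np.asarray(out, dtype=float)

        ours_by_locus = {lid: [] for lid in g.locus_sites}
        ac, _ = g.allele_counts()
        for a, lid in zip(ac, g.locus_ids):
            ours_by_locus[lid].append(a)
        ours = per_locus_stats(ours_by_locus.values())

        rng = np.random.default_rng(4)
        reps = msprime.sim_ancestry(samples={"pop0": 10},
                                    demography=sim._demography(scn),
                                    sequence_length=74, ploidy=2,
                                    num_replicates=n_loci, random_seed=5)
        ref_rows = []
        for ts in reps:
            mts = msprime.sim_mutations(ts, rate=scn.mu,
                                        model=msprime.BinaryMutationModel(),
                                        discrete_genome=False,
                                        random_seed=int(rng.integers(1, 2**31)))
            ref_rows.append(mts.genotype_matrix().sum(axis=1)
                            if mts.num_sites else [])
        ref = per_locus_stats(ref_rows)

        for k, name in enumerate(("S", "singletons", "pi")):
            diff = ours[:, k].mean() - ref[:, k].mean()
            se = np.sqrt(ours[:, k].var() / len(ours) + ref[:, k].var() / len(ref))
            assert abs(diff) < 4 * se, f"{name}: diff {diff:.4f}, se {se:.4f}"

    def test_folded_sfs_goodness_of_fit(self):
        from urbanpopgen import demography as dem

        scn = sim.scenario_preset("null_panmixia", n_individuals=20, n_loci=2500,
                                  seed=6)
        g, _ = sim.simulate_coalescent(scn)
        sfs = dem.build_folded_sfs(g, n_chrom=40, seed=7)
        n = 40
        exp = 1.0 / np.arange(1, n // 2 + 1) + 1.0 / (n - np.arange(1, n // 2 + 1))
        exp[-1] /= 2.0
        exp = exp / exp.sum() * sfs.counts.sum()
        chi = stats.chisquare(sfs.counts, exp)
        assert chi.pvalue > 0.01


class TestTwoHabitat:
    def test_null_preset_fst_near_zero(self):
        scn = sim.scenario_preset("null_panmixia", n_individuals=24, n_loci=1500,
                                  seed=8)
        g, truth = sim.simulate_coalescent(scn)
        labels = ["urban"] * 12 + ["rural"] * 12
        fst = _two_group_fst(g, labels)
        assert abs(fst) < 0.02
        assert truth["expected_fst"] == 0.0

    def test_fragmentation_exceeds_facilitation(self):
        vals = {}
        for name in ("fragmentation", "facilitation"):
            scn = sim.scenario_preset(name, n_individuals=24, n_loci=800, seed=9)
            g, labels, truth = sim.simulate_two_habitat(scn)
            vals[name] = (_two_group_fst(g, list(labels)), truth["expected_fst"])
        assert vals["fragmentation"][0] > vals["facilitation"][0]
        for fst, expected in vals.values():
            assert fst == pytest.approx(expected, abs=0.05)


def _two_group_fst(g, labels):
    from urbanpopgen.differentiation import hudson_fst_pair
    from urbanpopgen.geno_io import group_indices

    freqs = {}
    for lab, idx in group_indices(g, labels).items():
        ac, an = g.allele_counts(idx)
        freqs[lab] = (np.where(an > 0, ac / np.maximum(an, 1), np.nan),
                      an.astype(float))
    (p1, n1), (p2, n2) = freqs.values()
    ok = np.isfinite(p1) & np.isfinite(p2) & (n1 > 1) & (n2 > 1)
    return hudson_fst_pair(p1[ok], p2[ok], n1[ok], n2[ok])


class TestLandscape:
    def test_counts_and_constraints(self):
        frame = sim.simulate_landscape(n_urban_sites=63, n_rural_sites=61, seed=1)
        sites = frame.drop_duplicates("site_id")
        urban = sites[sites.habitat_by_distance == "urban"]
        rural = sites[sites.habitat_by_distance == "rural"]
        assert len(urban) == 63 and len(rural) == 61
        assert (urban.dist_km <= 30).all()
        assert (rural.dist_km > 30).all()
        counts = frame.groupby("site_id").size()
        assert counts.between(1, 5).all()

    def test_within_site_spacing_over_3m(self):
        frame = sim.simulate_landscape(n_urban_sites=10, n_rural_sites=10, seed=2)
        for _, sub in frame.groupby("site_id"):
            if len(sub) < 2:
                continue
            lat, lon = sub.lat.values, sub.lon.values
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    d_m = urban_class.haversine_km(lat[i], lon[i],
                                                   lat[j], lon[j]) * 1000.0
                    assert d_m > 3.0

    def test_deterministic(self):
        a = sim.simulate_landscape(seed=3)
        b = sim.simulate_landscape(seed=3)
        assert a.equals(b)


class TestMissingnessAndSibs:
    def test_noop_identity(self, small_panmictic):
        g, _ = small_panmictic
        g2, info = sim.add_missingness_and_sibs(g, miss_rate=0.0, n_sib_pairs=0,
                                                seed=1)
        np.testing.assert_array_equal(g.genotypes, g2.genotypes)
        assert info["sib_pairs"] == []

    def test_missing_fraction_binomial(self, small_panmictic):
        g, _ = small_panmictic
        g2, _ = sim.add_missingness_and_sibs(g, miss_rate=0.3, seed=2)
        frac = np.mean(g2.genotypes == geno_io.MISSING)
        assert frac == pytest.approx(0.3, abs=0.02)
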