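import numpy as np
import pandas as pd
import pytest

from urbanpopgen import geno_io, simulate as sim
from urbanpopgen.geno_io import MISSING, FilterConfig, filter_snps

from conftest import (TOY_EXPECTED_PERMISSIVE, TOY_EXPECTED_STRICT, make_matrix)


TOY_VCF = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampA\tsampB
1\t10\tlocA\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1
1\t20\tlocB\tC\tG\t.\tPASS\t.\tGT\t0/1\t1/1
1\t25\tlocC\tC\tG,A\t.\tPASS\t.\tGT\t0/1\t1/2
1\t30\tlocD\tG\tA\t.\tPASS\t.\tGT\t./.\t1/1
"""


class TestReadVcf:
    def test_direct_transcription(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(TOY_VCF)
        g = geno_io.read_vcf(path)
        # triallelic record at pos 25 skipped
        assert g.n_snps == 3
        assert list(g.pos) == [10, 20, 30]
        np.testing.assert_array_equal(g.genotypes[:, 0], [0, 1])
        np.testing.assert_array_equal(g.genotypes[:, 1], [1, 2])
        np.testing.assert_array_equal(g.genotypes[:, 2], [MISSING, 2])
        assert list(g.locus_ids) == ["locA", "locB", "locD"]

    def test_unknown_sample_is_hard_error(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(TOY_VCF)
        meta = pd.DataFrame({"sample_id": ["sampA"], "site_id": ["s1"],
                             "lat": [43.0], "lon": [-79.0]})
        with pytest.raises(ValueError, match="sampB"):
            geno_io.read_vcf(path, metadata=meta)

    def test_round_trip_preserves_codes(self, tmp_path, small_panmictic):
        g, _ = small_panmictic
        out = tmp_path / "sim.vcf"
        geno_io.write_vcf(g, out)
        g2 = geno_io.read_vcf(out, locus_sites=g.locus_sites)
        np.testing.assert_array_equal(g.genotypes, g2.genotypes)
        np.testing.assert_array_equal(g.pos, g2.pos)
        assert g.individual_ids == g2.individual_ids
        assert g.total_sites == g2.total_sites


class TestFilterSnps:
    def test_hand_enumerated_permissive(self, toy20):
        cfg = FilterConfig(mmaf=2 / 16, r=0.5, single_snp_per_locus=True)
        kept, report = filter_snps(toy20, cfg)
        assert sorted(kept.pos) == TOY_EXPECTED_PERMISSIVE
        assert len(report) == toy20.n_snps - len(TOY_EXPECTED_PERMISSIVE)

    def test_hand_enumerated_strict(self, toy20):
        cfg = FilterConfig(mmaf=0.05, r=0.75, single_snp_per_locus=True)
        kept, report = filter_snps(toy20, cfg)
        assert sorted(kept.pos) == TOY_EXPECTED_STRICT
        # the same locus can contribute different survivors per dataset
        assert 205 not in kept.pos and 220 in kept.pos

    def test_noop_settings_return_identity(self, toy20):
        kept, report = filter_snps(toy20, FilterConfig(mmaf=0.0, r=0.0))
        assert kept.n_snps == toy20.n_snps
        assert report.empty

    def test_monotone_in_thresholds(self, toy20):
        counts = {}
        for mmaf in (0.0, 0.05, 0.125, 0.2, 0.3):
            for r in (0.0, 0.5, 0.75, 1.0):
                kept, _ = filter_snps(toy20, FilterConfig(mmaf=mmaf, r=r))
                counts[(mmaf, r)] = kept.n_snps
        for (mmaf, r), c in counts.items():
            for (m2, r2), c2 in counts.items():
                if m2 >= mmaf and r2 >= r:
                    assert c2 <= c

    def test_strict_subset_of_permissive(self, small_panmictic):
        # at study scale the permissive MAF floor (2/n) sits below 0.05,
        # so the strict thresholds select a subset; the one-SNP-per-locus
        # step can swap survivors within a locus, so subsetness is a
        # threshold property and locus counts stay ordered
        g, _ = small_panmictic
        perm = FilterConfig(mmaf=2 / 256, r=0.5)
        strict = FilterConfig(mmaf=0.05, r=0.75)
        k1, _ = filter_snps(g, perm)
        k2, _ = filter_snps(g, strict)
        assert set(k2.pos).issubset(set(k1.pos))
        k1s, _ = filter_snps(g, FilterConfig(mmaf=2 / 256, r=0.5,
                                             single_snp_per_locus=True))
        k2s, _ = filter_snps(g, FilterConfig(mmaf=0.05, r=0.75,
                                             single_snp_per_locus=True))
        assert k2s.n_snps <= k1s.n_snps


class TestRelatedness:
    def test_identical_individuals_outside_halfsib_band(self):
        rng = np.random.default_rng(0)
        geno = rng.binomial(2, 0.4, size=(10, 400)).astype(np.int8)
        geno[1] = geno[0]  # clone pair
        g = make_matrix(geno)
        rel = geno_io.pairwise_relatedness(g)
        pair = rel[(rel.id_a == "i000") & (rel.id_b == "i001")]
        assert pair["relatedness"].iloc[0] > 0.9
        pruned, report = geno_io.relatedness_prune(g, (0.25, 0.75))
        assert "i000" in pruned.individual_ids and "i001" in pruned.individual_ids

    def test_planted_sibs_are_top_pairs_and_pruned(self):
        scn = sim.scenario_preset("null_panmixia", n_individuals=30, n_loci=3000,
                                  seed=5)
        g, _ = sim.simulate_coalescent(scn)
        g2, info = sim.add_missingness_and_sibs(g, n_sib_pairs=2, seed=6)
        rel = geno_io.pairwise_relatedness(g2)
        top = rel.nlargest(2, "relatedness")
        found = {tuple(sorted(p)) for p in zip(top.id_a, top.id_b)}
        planted = {tuple(sorted(p)) for p in info["sib_pairs"]}
        assert found == planted
        pruned, report = geno_io.relatedness_prune(g2)
        assert len(report) == 2
        for a, b in planted:
            assert (a in pruned.individual_ids) != (b in pruned.individual_ids)

    def test_unrelated_sample_not_pruned(self):
        scn = sim.scenario_preset("null_panmixia", n_individuals=30, n_loci=3000,
                                  seed=8)
        g, _ = sim.simulate_coalescent(scn)
        _, report = geno_io.relatedness_prune(g)
        assert len(report) == 0


class TestAlleleFrequencies:
    def test_single_heterozygote(self):
        g = make_matrix([[1]], ids=["solo"])
        tab = geno_io.allele_frequencies(g, ["grp"])
        assert tab["alt_freq"].iloc[0] == 0.5
        assert tab["n_copies"].iloc[0] == 2

    def test_all_missing_flagged_undefined(self):
        g = make_matrix([[MISSING], [MISSING]])
        tab = geno_io.allele_frequencies(g, ["a", "a"])
        assert np.isnan(tab["alt_freq"].iloc[0])
        assert tab["n_copies"].iloc[0] == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        geno = rng.integers(-1, 3, size=(12, 40)).astype(np.int8)
        g = make_matrix(geno)
        labels = ["a"] * 5 + ["b"] * 7
        tab = geno_io.allele_frequencies(g, labels)
        for lab, rows in (("a", range(5)), ("b", range(5, 12))):
            sub = tab[tab.group == lab]
            for j in range(40):
                calls = [geno[i, j] for i in rows if geno[i, j] != MISSING]
                copies = 2 * len(calls)
                assert sub["n_copies"].iloc[j] == copies
                if copies:
                    assert sub["alt_freq"].iloc[j] == pytest.approx(sum(calls) / copies)
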