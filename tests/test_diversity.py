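import numpy as np
import pytest

from polypopgen.diversity import (
    _expected_alleles,
    allele_frequencies,
    allelic_richness,
    gene_diversity,
    inbreeding_coefficients,
    private_alleles,
    total_gene_diversity,
)
from polypopgen.genotypes import Genotype, GenotypeMatrix, Locus


def _gm(cells_by_pop, locus=None):
    """Build a one-locus matrix from {pop: [genotypes]}."""
    locus = locus or Locus("L", 3, (100, 200))
    inds, cells, pops = [], [], {}
    for pop, gs in cells_by_pop.items():
        for k, g in enumerate(gs):
            name = f"{pop}_{k}"
            inds.append(name)
            pops[name] = pop
            cells.append([g])
    return GenotypeMatrix(inds, [locus], cells, pops)


class TestAlleleFrequencies:
    def test_dosage_known_counts(self):
        gm = _gm({"P": [Genotype((150, 150, 153, 153), dosage_known=True)]})
        t = allele_frequencies(gm)
        assert t.freqs[("P", "L")] == {150: 0.5, 153: 0.5}
        assert t.copies[("P", "L")] == 4

    def test_equal_split_on_ambiguous_cell(self):
        gm = _gm({"P": [Genotype((150, 153))]})
        t = allele_frequencies(gm, "equal-split")
        assert t.freqs[("P", "L")] == {150: 0.5, 153: 0.5}
        assert t.counts[("P", "L")] == {150: 2.0, 153: 2.0}

    def test_known_only_excludes_ambiguous(self):
        gm = _gm({"P": [Genotype((150, 153)), Genotype((156,) * 4, dosage_known=True)]})
        t = allele_frequencies(gm, "known-only")
        assert t.freqs[("P", "L")] == {156: 1.0}
        assert t.copies[("P", "L")] == 4

    def test_two_fixed_individuals(self):
        gm = _gm({"P": [Genotype((150,) * 4, dosage_known=True),
                        Genotype((153,) * 4, dosage_known=True)]})
        t = allele_frequencies(gm)
        assert t.freqs[("P", "L")] == {150: 0.5, 153: 0.5}
        assert t.copies[("P", "L")] == 8

    def test_empty_cell_flagged(self):
        gm = _gm({"P": [Genotype(())], "Q": [Genotype((150,) * 4, dosage_known=True)]})
        t = allele_frequencies(gm)
        assert ("P", "L") in t.empty_cells
        assert t.freqs[("P", "L")] == {}


class TestGeneDiversity:
    def test_monomorphic_is_zero(self):
        assert gene_diversity({150: 1.0}, 8) == 0.0

    def test_unbiased_closed_form(self):
        # two alleles at 0.5 with 8 copies: (8/7)(1-0.5)
        assert gene_diversity({1: 0.5, 2: 0.5}, 8) == pytest.approx(8 / 7 * 0.5)

    def test_undefined_below_two_copies(self):
        assert np.isnan(gene_diversity({1: 1.0}, 1))

    def test_relabelling_invariance(self, rng):
        p = rng.dirichlet(np.ones(6))
        f1 = {a: float(x) for a, x in enumerate(p)}
        f2 = {a + 100: float(x) for a, x in enumerate(p)}
        assert gene_diversity(f1, 20) == pytest.approx(gene_diversity(f2, 20))


class TestAllelicRichness:
    def test_rarefaction_matches_exhaustive_enumeration(self):
        """counts {A:3, B:1}, g=2: enumerate all C(4,2) subsamples."""
        from itertools import combinations

        copies = ["A", "A", "A", "B"]
        expected = np.mean([len(set(c)) for c in combinations(copies, 2)])
        got = _expected_alleles(np.array([3.0, 1.0]), 2)
        assert got == pytest.approx(expected)  # = 1.5
        assert got == pytest.approx(1.5)

    def test_g_equal_n_returns_observed_count(self):
        assert _expected_alleles(np.array([3.0, 1.0]), 4) == pytest.approx(2.0)

    def test_ar_below_na_with_rare_alleles(self):
        gm = _gm({"P": [Genotype((150, 150, 150, 153), dosage_known=True),
                        Genotype((150,) * 4, dosage_known=True)],
                  "Q": [Genotype((150, 153, 156, 159), dosage_known=True)]})
        t = allele_frequencies(gm)
        ar = allelic_richness(t, g=4)
        assert ar.loc["P", "L"] < 2.0  # NA(P)=2 but the rare allele thins out
        assert ar.loc["Q", "L"] == pytest.approx(4.0)

    def test_monotone_in_g(self):
        t_counts = np.array([5.0, 2.0, 1.0])
        vals = [_expected_alleles(t_counts, g) for g in range(2, 9)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestTotalsAndPrivate:
    def test_ht_two_fixed_populations(self):
        gm = _gm({"P": [Genotype((150,) * 4, dosage_known=True)] * 3,
                  "Q": [Genotype((153,) * 4, dosage_known=True)] * 3})
        # mean freqs 0.5/0.5 over 24 copies: (24/23)(1-0.5)
        assert total_gene_diversity(allele_frequencies(gm)) == pytest.approx(24 / 23 * 0.5)

    def test_ht_equals_mean_he_when_pops_identical(self, rng):
        g = [Genotype((150, 153, 156, 159), dosage_known=True),
             Genotype((150, 150, 153, 156), dosage_known=True)]
        gm = _gm({"P": g, "Q": g})
        t = allele_frequencies(gm)
        he = gene_diversity(t.freqs[("P", "L")], 16)  # both pops pooled copies
        assert total_gene_diversity(t) == pytest.approx(he, rel=1e-9)

    def test_private_alleles_definition(self):
        gm = _gm({"P": [Genotype((150, 153, 156, 159), dosage_known=True)],
                  "Q": [Genotype((150, 162))]})
        pa = private_alleles(allele_frequencies(gm))
        # alleles: 150 shared; 153,156,159 private to P; 162 private to Q (5 total)
        assert pa["P"] == pytest.approx(100 * 3 / 5)
        assert pa["Q"] == pytest.approx(100 * 1 / 5)
        assert pa["total"] == pytest.approx(pa["P"] + pa["Q"])

    def test_per_population_sums_to_total(self, rng):
        from polypopgen.simulate import SimulationConfig, simulate_hierarchical

        gm, _ = simulate_hierarchical(SimulationConfig(
            n_clusters=2, populations_per_cluster=(2, 2),
            individuals_per_population=(6, 8, 7, 6), n_loci=3, seed=5))
        pa = private_alleles(allele_frequencies(gm))
        assert pa.drop("total").sum() == pytest.approx(pa["total"])


class TestInbreeding:
    def test_homozygous_individual_positive_fi(self):
        gs = [Genotype((150,) * 4, dosage_known=True)] + [
            Genotype((150, 153, 156, 159), dosage_known=True) for _ in range(5)
        ]
        gm = _gm({"P": gs})
        res = inbreeding_coefficients(gm, permutations=0)
        assert res.fi_individual["P_0"] > 0

    def test_fully_heterozygous_individual_negative_fi(self):
        gs = [Genotype((150, 153, 156, 159), dosage_known=True),
              Genotype((150, 150, 150, 153), dosage_known=True),
              Genotype((153, 153, 156, 156), dosage_known=True)]
        gm = _gm({"P": gs})
        res = inbreeding_coefficients(gm, permutations=0)
        assert res.fi_individual["P_0"] < 0

    def test_permutation_null_centred_at_zero(self):
        """Under random union of gametes FIS is ~0 and the permutation test
        rejects at roughly its nominal 5% rate."""
        rng = np.random.default_rng(11)
        sizes = np.array([150, 153, 156, 159, 162, 165])
        p = np.array([0.3, 0.25, 0.2, 0.1, 0.1, 0.05])
        fis, rej = [], 0
        for t in range(20):
            gs = [Genotype(tuple(sorted(rng.choice(sizes, 4, p=p))), dosage_known=True)
                  for _ in range(40)]
            gm = _gm({"P": gs})
            res = inbreeding_coefficients(gm, permutations=99, seed=t)
            fis.append(res.fis_multilocus)
            rej += res.fis_pvalue <= 0.05
        assert abs(np.mean(fis)) < 0.05
        assert rej <= 4  # binomial(20, 0.05) upper tail

    def test_monomorphic_population_contributes_nothing(self):
        gm = _gm({"P": [Genotype((150,) * 4, dosage_known=True)] * 4})
        res = inbreeding_coefficients(gm, permutations=0)
        assert np.isnan(res.fis_multilocus)


class TestAlternativePaDenominator:
    def test_own_denominator_flag(self):
        gm = _gm({"P": [Genotype((150, 153, 156, 159), dosage_known=True)],
                  "Q": [Genotype((150, 162))]})
        t = allele_frequencies(gm)
        pa = private_alleles(t, denominator="own")
        # P holds 4 alleles, 3 private; Q holds 2 alleles, 1 private
        assert pa["P"] == pytest.approx(100 * 3 / 4)
        assert pa["Q"] == pytest.approx(100 * 1 / 2)

    def test_band_count_per_locus_equals_na(self):
        """Dominant band count per locus equals the diversity module's total
        allele count at that locus."""
        from polypopgen.genotypes import to_dominant
        from polypopgen.simulate import SimulationConfig, simulate_hierarchical

        gm, _ = simulate_hierarchical(SimulationConfig(
            n_clusters=2, populations_per_cluster=(1, 1),
            individuals_per_population=(8, 8), n_loci=3, seed=2))
        t = allele_frequencies(gm)
        dm = to_dominant(gm)
        for locus in gm.loci:
            n_bands = sum(1 for l, _ in dm.bands if l == locus.name)
            assert n_bands == len(t.alleles_at(locus.name))
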