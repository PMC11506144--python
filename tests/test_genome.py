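"""Founder simulation, LD structure, QC filters and the HWE exact test."""

import numpy as np
import pytest
from scipy.special import gammaln

import mtgblup as mg
from mtgblup.genome import DosageMatrix, VariantRecord, allele_frequencies


def _variants(n, chrom="1"):
    return [VariantRecord(chrom=chrom, snp_id=f"s{j}", bp=100 * (j + 1)) for j in range(n)]


class TestSimulateFounders:
    def test_independent_snps_at_rho_zero(self):
        panel = mg.simulate_founders(500, n_chrom=1, snps_per_chrom=20, adjacency_rho=0.0, seed=3)
        d = panel.dosages().values.astype(float)
        r = [np.corrcoef(d[:, j], d[:, j + 1])[0, 1] for j in range(19)]
        assert abs(np.mean(r)) < 0.03

    def test_adjacent_haplotype_correlation_matches_copy_rate(self):
        # Markov copy process: adjacent correlation ~ adjacency_rho
        panel = mg.simulate_founders(2000, n_chrom=1, snps_per_chrom=1000, adjacency_rho=0.9, seed=4)
        h = panel.haplotypes.reshape(-1, panel.n_snps).astype(float)
        r = [np.corrcoef(h[:, j], h[:, j + 1])[0, 1] for j in range(panel.n_snps - 1)]
        assert abs(np.mean(r) - 0.9) < 0.03

    def test_deterministic_given_seed(self):
        a = mg.simulate_founders(50, n_chrom=2, snps_per_chrom=30, seed=9)
        b = mg.simulate_founders(50, n_chrom=2, snps_per_chrom=30, seed=9)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert a.ids == b.ids and np.array_equal(a.sex, b.sex)

    def test_ld_ladder_has_partners_at_all_targets(self, founders_2k):
        # interior loci must see partners near r = 0.2, 0.5 and 0.8 within
        # +/-50 SNPs, the substrate the QTL-pairing step relies on
        d = founders_2k.dosages().values.astype(float)
        sl = founders_2k.chrom_slices()["1"]
        z = d[:, sl] - d[:, sl].mean(axis=0)
        z /= np.linalg.norm(z, axis=0)
        rng = np.random.default_rng(0)
        interior = rng.choice(np.arange(60, 940), size=150, replace=False)
        hits = {0.2: 0, 0.5: 0, 0.8: 0}
        for q in interior:
            r = z[:, q - 50 : q + 51].T @ z[:, q]
            for t in hits:
                if np.any(np.abs(np.abs(r) - t) <= 0.05):
                    hits[t] += 1
        for t, n_hit in hits.items():
            assert n_hit >= 0.95 * len(interior), f"LD target {t} unavailable"

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            mg.simulate_founders(10, snps_per_chrom=1)
        with pytest.raises(ValueError):
            mg.simulate_founders(10, adjacency_rho=1.0)
        with pytest.raises(ValueError):
            mg.simulate_founders(10, maf_low=0.7)


class TestLdR:
    def test_identity_and_complement(self):
        x = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        assert mg.ld_r(x, x) == pytest.approx(1.0)
        assert mg.ld_r(x, 2 - x) == pytest.approx(-1.0)

    def test_matches_hand_computed_pearson(self):
        # 6 individuals, by-hand Pearson correlation
        x = np.array([0.0, 1.0, 2.0, 2.0, 1.0, 0.0])
        y = np.array([1.0, 1.0, 2.0, 2.0, 0.0, 0.0])
        mx, my = x - 1.0, y - 1.0
        expected = (mx @ my) / np.sqrt((mx @ mx) * (my @ my))
        assert mg.ld_r(x, y) == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            mg.ld_r(np.ones(5), np.arange(5.0))


def _hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Brute-force exact HWE p-value over all heterozygote configurations."""
    n = n_AA + n_Aa + n_aa
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    def logprob(het):
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        return (
            gammaln(n + 1) - gammaln(het + 1) - gammaln(hom_r + 1) - gammaln(hom_c + 1)
            + het * np.log(2) + gammaln(n_rare + 1) + gammaln(2 * n - n_rare + 1)
            - gammaln(2 * n + 1)
        )
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    lp = np.array([logprob(h) for h in hets])
    p = np.exp(lp - lp.max())
    p /= p.sum()
    obs = p[hets == n_Aa][0]
    return min(1.0, p[p <= obs * (1 + 1e-12)].sum())


class TestHwe:
    def test_perfect_equilibrium(self):
        assert mg.hwe_pvalue(25, 50, 25) > 0.5

    def test_all_heterozygote_extreme(self):
        assert mg.hwe_pvalue(0, 100, 0) < 1e-5

    def test_degenerate_single_genotype(self):
        assert mg.hwe_pvalue(1, 0, 0) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "counts",
        [(10, 20, 20), (5, 5, 40), (0, 10, 15), (12, 1, 12), (3, 30, 2), (60, 10, 30)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert mg.hwe_pvalue(*counts) == pytest.approx(_hwe_enumeration_oracle(*counts), rel=1e-10)

    def test_chisq_variant_reasonable(self):
        exact = mg.hwe_pvalue(60, 10, 30)
        chisq = mg.hwe_pvalue(60, 10, 30, method="chisq")
        assert exact < 1e-5 and chisq < 1e-5

    def test_input_validation(self):
        with pytest.raises(ValueError):
            mg.hwe_pvalue(0, 0, 0)
        with pytest.raises(ValueError):
            mg.hwe_pvalue(-1, 2, 3)


class TestQcFilter:
    def _toy(self, values):
        values = np.asarray(values, dtype=np.int8)
        return DosageMatrix(
            values=values,
            ids=[f"i{k}" for k in range(values.shape[0])],
            variants=_variants(values.shape[1]),
        )

    def test_clean_matrix_untouched(self):
        # MAF 0.5 and perfect HWE proportions: nothing to remove
        block = np.array([[0], [1], [1], [2]], dtype=np.int8)
        dm = self._toy(np.tile(block, (25, 3)))
        out, report = mg.qc_filter(dm)
        assert out.values.shape == dm.values.shape
        assert report.removed_maf == report.removed_hwe == 0
        assert report.removed_ind_call == report.removed_snp_call == 0

    def test_monomorphic_snp_removed_by_maf(self):
        block = np.array([[0], [1], [1], [2]], dtype=np.int8)
        vals = np.tile(block, (25, 2))
        vals = np.column_stack([vals, np.zeros(100, dtype=np.int8)])
        out, report = mg.qc_filter(self._toy(vals))
        assert report.removed_maf == 1
        assert out.n_snps == 2

    def test_hwe_outlier_removed(self):
        # genotype counts AA=60, Aa=10, aa=30 -> exact p far below 1e-5
        assert mg.hwe_pvalue(60, 10, 30) < 1e-5
        col = np.array([2] * 60 + [1] * 10 + [0] * 30, dtype=np.int8)
        block = np.array([[0], [1], [1], [2]], dtype=np.int8)
        vals = np.column_stack([np.tile(block, (25, 2)), col])
        out, report = mg.qc_filter(self._toy(vals))
        assert report.removed_hwe == 1
        assert out.n_snps == 2

    def test_call_rate_filters_and_order(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(0, 3, size=(40, 40)).astype(np.int8)
        vals[0, :30] = mg.genome.MISSING  # individual call rate 25%
        vals[1:, 3] = mg.genome.MISSING  # SNP dead only after ind removal
        out, report = mg.qc_filter(self._toy(vals), maf=0.0, hwe_p=0.0)
        assert report.removed_ind_call == 1
        assert report.removed_snp_call == 1
        assert out.n_individuals == 39

    def test_idempotent(self, founders_small):
        dm = founders_small.dosages()
        once, _ = mg.qc_filter(dm)
        twice, rep2 = mg.qc_filter(once)
        assert np.array_equal(once.values, twice.values)
        assert rep2.removed_maf == rep2.removed_hwe == 0

    def test_all_removed_is_an_error(self):
        vals = np.zeros((20, 3), dtype=np.int8)
        with pytest.raises(ValueError, match="all SNPs removed"):
            mg.qc_filter(self._toy(vals))


def test_allele_frequencies_ignore_missing():
    vals = np.array([[0, 2], [1, mg.genome.MISSING], [2, 2]], dtype=np.int8)
    f = allele_frequencies(vals)
    assert f[0] == pytest.approx(0.5)
    assert f[1] == pytest.approx(1.0)
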