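"""Synthetic founder genomes, genotype QC and linkage disequilibrium.

The founder generator produces phased diploid biallelic haplotypes whose
intra-chromosomal linkage disequilibrium (LD) decays geometrically with
marker distance.  Each haplotype is drawn from a first-order Markov "copy"
process along the chromosome: the allele at SNP j equals the allele at
SNP j-1 with probability ``adjacency_rho`` and is otherwise redrawn from
that SNP's marginal alternate-allele frequency.  Adjacent haplotype
correlation is therefore close to ``adjacency_rho`` and the signed dosage
correlation between loci k apart decays roughly like ``adjacency_rho**k``,
which guarantees that every interior locus has nearby partners at any
requested LD level between ~0 and ``adjacency_rho``.

LD throughout this package is the SIGNED Pearson correlation of allele
dosages (not r^2): the trait simulator gives locus pairs identical signed
effects, so the induced genetic correlation equals the signed dosage
correlation of the pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

MISSING = -1  # missing dosage code (PLINK reader / QC path only)

__all__ = [
    "MISSING",
    "VariantRecord",
    "HaplotypePanel",
    "DosageMatrix",
    "QCReport",
    "simulate_founders",
    "qc_filter",
    "hwe_pvalue",
    "ld_r",
    "allele_frequencies",
]


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNP on the marker map."""

    chrom: str
    snp_id: str
    bp: int
    allele_ref: str = "A"
    allele_alt: str = "B"


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes for a set of individuals.

    ``haplotypes`` has shape (n_individuals, 2, n_snps) with entries in
    {0, 1}; 1 codes the alternate allele.  ``sex`` holds 'M'/'F' labels.
    """

    ids: list[str]
    sex: np.ndarray
    haplotypes: np.ndarray
    variants: list[VariantRecord]

    def __post_init__(self) -> None:
        n, two, m = self.haplotypes.shape
        if two != 2:
            raise ValueError("haplotypes must have shape (n, 2, m)")
        if len(self.ids) != n or len(self.sex) != n:
            raise ValueError("ids/sex length must match haplotype count")
        if len(self.variants) != m:
            raise ValueError("variant list must match haplotype length")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[2]

    def dosages(self) -> "DosageMatrix":
        """Alternate-allele dosage (0/1/2) matrix for the panel."""
        d = self.haplotypes.sum(axis=1).astype(np.int8)
        return DosageMatrix(values=d, ids=list(self.ids), variants=list(self.variants))

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous column slice per chromosome, in map order."""
        chroms = [v.chrom for v in self.variants]
        out: dict[str, slice] = {}
        start = 0
        for j in range(1, len(chroms) + 1):
            if j == len(chroms) or chroms[j] != chroms[start]:
                out[chroms[start]] = slice(start, j)
                start = j
        return out

    def subset(self, indices: np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(indices)
        return HaplotypePanel(
            ids=[self.ids[i] for i in idx],
            sex=self.sex[idx].copy(),
            haplotypes=self.haplotypes[idx].copy(),
            variants=list(self.variants),
        )


@dataclass
class DosageMatrix:
    """n_individuals x n_snps matrix of alternate-allele dosages.

    Values are in {0, 1, 2} with ``MISSING`` (-1) for missing genotypes.
    """

    values: np.ndarray
    ids: list[str]
    variants: list[VariantRecord]

    def __post_init__(self) -> None:
        ok = np.isin(self.values, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or the missing code")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


@dataclass
class QCReport:
    """Tally of individuals/SNPs removed by each quality-control filter."""

    n_individuals_in: int
    n_snps_in: int
    removed_ind_call: int = 0
    removed_snp_call: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def n_individuals_out(self) -> int:
        return self.n_individuals_in - self.removed_ind_call

    @property
    def n_snps_out(self) -> int:
        return (
            self.n_snps_in
            - self.removed_snp_call
            - self.removed_maf
            - self.removed_hwe
        )


def simulate_founders(
    n_individuals: int,
    n_chrom: int = 3,
    snps_per_chrom: int = 1000,
    chrom_length_bp: int = 100_000_000,
    adjacency_rho: float = 0.95,
    maf_low: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
    males_per_female: float = 1 / 9,
) -> HaplotypePanel:
    """Simulate a phased founder panel with geometric LD decay.

    Parameters
    ----------
    adjacency_rho
        Copy probability of the Markov process; adjacent haplotype
        correlation is ~adjacency_rho and LD at lag k decays like
        adjacency_rho**k.  Must lie in [0, 1).
    maf_low
        Marginal alternate-allele frequencies are drawn uniformly on
        [maf_low, 1 - maf_low].
    males_per_female
        Founder sex ratio; the default of 1:9 mirrors a pig nucleus herd
        with 500 boars per 4500 sows.  The first individuals are male.
    """
    if snps_per_chrom < 2:
        raise ValueError("snps_per_chrom must be at least 2")
    if not 0.0 <= adjacency_rho < 1.0:
        raise ValueError("adjacency_rho must lie in [0, 1)")
    if not 0.0 < maf_low <= 0.5:
        raise ValueError("maf_low must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)

    n_hap = 2 * n_individuals
    variants: list[VariantRecord] = []
    cols: list[np.ndarray] = []
    spacing = chrom_length_bp // (snps_per_chrom + 1)
    for c in range(1, n_chrom + 1):
        p = rng.uniform(maf_low, 1.0 - maf_low, size=snps_per_chrom)
        h = np.empty((n_hap, snps_per_chrom), dtype=np.uint8)
        h[:, 0] = rng.random(n_hap) < p[0]
        for j in range(1, snps_per_chrom):
            copy = rng.random(n_hap) < adjacency_rho
            fresh = (rng.random(n_hap) < p[j]).astype(np.uint8)
            h[:, j] = np.where(copy, h[:, j - 1], fresh)
        cols.append(h)
        for j in range(snps_per_chrom):
            variants.append(
                VariantRecord(chrom=str(c), snp_id=f"c{c}_s{j + 1}", bp=(j + 1) * spacing)
            )
    hap = np.concatenate(cols, axis=1).reshape(n_individuals, 2, -1)

    n_males = max(1, round(n_individuals * males_per_female / (1 + males_per_female)))
    sex = np.array(["M"] * n_males + ["F"] * (n_individuals - n_males))
    ids = [f"F{i + 1}" for i in range(n_individuals)]
    return HaplotypePanel(ids=ids, sex=sex, haplotypes=hap, variants=variants)


def allele_frequencies(dosages: np.ndarray) -> np.ndarray:
    """Observed alternate-allele frequency per SNP, ignoring missing entries."""
    d = np.asarray(dosages, dtype=float)
    mask = d != MISSING
    d = np.where(mask, d, 0.0)
    n_obs = mask.sum(axis=0)
    with np.errstate(invalid="ignore"):
        return d.sum(axis=0) / (2.0 * n_obs)


def ld_r(dosage_i: np.ndarray, dosage_j: np.ndarray) -> float:
    """Signed Pearson correlation of two dosage vectors (the LD measure used here)."""
    x = np.asarray(dosage_i, dtype=float)
    y = np.asarray(dosage_j, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors must have the same length")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("LD is undefined for a monomorphic locus (zero variance)")
    return float(np.corrcoef(x, y)[0, 1])


def hwe_pvalue(n_AA: int, n_Aa: int, n_aa: int, method: str = "exact") -> float:
    """Hardy-Weinberg equilibrium test p-value from genotype counts.

    ``method='exact'`` is the Wigginton/Cutler/Abecasis exact test (the sum
    of probabilities of all heterozygote configurations no more probable
    than the observed one, conditional on the allele counts) as used by
    PLINK 1.9 by default.  ``method='chisq'`` is the 1-df chi-square test.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotyped individual required")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # rare-allele count
    if method == "chisq":
        p = (2 * n_AA + n_Aa) / (2 * n)
        exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
        obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
        if np.any(exp == 0):
            return 1.0
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        return float(stats.chi2.sf(chi2, df=1))
    if method != "exact":
        raise ValueError(f"unknown HWE method {method!r}")

    # Conditional distribution of the heterozygote count given allele counts,
    # built by the standard two-sided recurrence from the mode.
    het_probs = _hwe_het_distribution(n, n_rare)
    obs_p = het_probs[n_Aa]
    return float(min(1.0, het_probs[het_probs <= obs_p * (1 + 1e-12)].sum()))


def _hwe_het_distribution(n: int, n_rare: int) -> np.ndarray:
    """P(het count | sample size n, rare-allele count) for all feasible counts."""
    probs = np.zeros(n_rare + 1)
    mid = int(round(n_rare * (2 * n - n_rare) / (2.0 * n)))
    if mid % 2 != n_rare % 2:
        mid += 1 if mid < n_rare else -1
    probs[mid] = 1.0
    # downward recurrence: het -> het - 2
    het = mid
    while het >= 2:
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        probs[het - 2] = probs[het] * het * (het - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        het -= 2
    # upward recurrence: het -> het + 2
    het = mid
    while het <= n_rare - 2:
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        probs[het + 2] = probs[het] * 4.0 * hom_r * hom_c / ((het + 2) * (het + 1))
        het += 2
    return probs / probs.sum()


def qc_filter(
    dosages: DosageMatrix,
    ind_call: float = 0.95,
    snp_call: float = 0.95,
    maf: float = 0.05,
    hwe_p: float = 1e-5,
    hwe_method: str = "exact",
) -> tuple[DosageMatrix, QCReport]:
    """Apply the standard genotype QC cascade.

    Individuals with call rate below ``ind_call`` are removed first; the
    SNP filters (call rate, minor-allele frequency, Hardy-Weinberg exact
    test) are then applied jointly on the remaining individuals.
    """
    for name, t in (("ind_call", ind_call), ("snp_call", snp_call), ("maf", maf), ("hwe_p", hwe_p)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"threshold {name} must lie in [0, 1]")
    d = dosages.values
    report = QCReport(
        n_individuals_in=dosages.n_individuals,
        n_snps_in=dosages.n_snps,
        thresholds={"ind_call": ind_call, "snp_call": snp_call, "maf": maf, "hwe_p": hwe_p},
    )

    present = d != MISSING
    keep_ind = present.mean(axis=1) >= ind_call
    report.removed_ind_call = int((~keep_ind).sum())
    d = d[keep_ind]
    present = present[keep_ind]

    call = present.mean(axis=0)
    ok_call = call >= snp_call
    report.removed_snp_call = int((~ok_call).sum())

    freq = allele_frequencies(d)
    maf_obs = np.minimum(freq, 1.0 - freq)
    ok_maf = ok_call & (maf_obs >= maf)
    report.removed_maf = int((ok_call & ~ok_maf).sum())

    ok_hwe = ok_maf.copy()
    for j in np.flatnonzero(ok_maf):
        col = d[:, j]
        col = col[col != MISSING]
        counts = np.bincount(col, minlength=3)
        if hwe_pvalue(counts[2], counts[1], counts[0], method=hwe_method) < hwe_p:
            ok_hwe[j] = False
    report.removed_hwe = int((ok_maf & ~ok_hwe).sum())

    if not ok_hwe.any():
        raise ValueError("all SNPs removed by QC; relax the thresholds")
    out = DosageMatrix(
        values=d[:, ok_hwe].copy(),
        ids=[i for i, k in zip(dosages.ids, keep_ind) if k],
        variants=[v for v, k in zip(dosages.variants, ok_hwe) if k],
    )
    return out, report
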