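"""Simulation of genetically correlated trait pairs via LD-matched QTL pairs.

The genetic correlation between the two traits of a pair is induced
purely by linkage disequilibrium: trait-A QTLs are drawn uniformly from
the segregating loci, each is matched with a nearby partner locus whose
signed dosage correlation is close to the target, and both members of a
pair receive the SAME signed effect, sampled as a gamma(0.4, 2/3)
magnitude with a random sign.  With identical effects, each pair
contributes genetic covariance proportional to its dosage correlation,
so the correlation of the two true-breeding-value (TBV) vectors
approaches the LD target.

TBV_i = sum_j effect_j * dosage_ij over the trait's QTLs.  The residual
variance is set from the realized additive variance V_g by
h2 = V_g / (V_g + V_e), and phenotypes are TBV plus independent
N(0, V_e) residuals, so realized heritability matches the requested one
up to residual sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import HaplotypePanel

__all__ = [
    "TraitSpec",
    "QTLPairSet",
    "TraitData",
    "sample_qtls",
    "pair_qtls",
    "sample_effects",
    "compute_tbv",
    "residual_variance",
    "simulate_trait_pair",
    "PairingError",
]


class PairingError(RuntimeError):
    """No partner locus satisfying the LD target could be found."""


@dataclass(frozen=True)
class TraitSpec:
    """Genetic architecture of one simulated trait."""

    h2: float
    n_qtl: int = 500
    gamma_shape: float = 0.4
    gamma_scale: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie in (0, 1)")
        if self.n_qtl < 1:
            raise ValueError("n_qtl must be at least 1")


@dataclass
class QTLPairSet:
    """LD-matched QTL pairs and their shared signed effects."""

    qtl_a: np.ndarray
    qtl_b: np.ndarray
    target_r: float
    realized_r: np.ndarray
    effects: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.qtl_a) != len(self.qtl_b):
            raise ValueError("qtl_a and qtl_b must pair one-to-one")
        if set(self.qtl_a.tolist()) & set(self.qtl_b.tolist()):
            raise ValueError("a locus cannot be a QTL for both traits")

    def to_text(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("index_a\tindex_b\teffect\trealized_r\n")
            eff = self.effects if self.effects is not None else np.full(len(self.qtl_a), np.nan)
            for a, b, e, r in zip(self.qtl_a, self.qtl_b, eff, self.realized_r):
                fh.write(f"{a}\t{b}\t{e:.6g}\t{r:.4f}\n")


@dataclass
class TraitData:
    """Per-individual TBV and phenotype for one trait."""

    tbv: np.ndarray
    phenotype: np.ndarray
    v_g: float
    v_e: float
    h2: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if self.v_g <= 0 or self.v_e <= 0:
            raise ValueError("variances must be positive")
        if self.tbv.shape != self.phenotype.shape:
            raise ValueError("tbv and phenotype must align")


def sample_qtls(
    panel_or_dosages: HaplotypePanel | np.ndarray,
    n_qtl: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample QTL column indices uniformly from the segregating loci."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = _dosage_array(panel_or_dosages)
    segregating = np.flatnonzero(d.std(axis=0) > 0)
    if segregating.size < n_qtl:
        raise ValueError(
            f"only {segregating.size} segregating loci available for {n_qtl} QTLs"
        )
    return np.sort(rng.choice(segregating, size=n_qtl, replace=False))


def _dosage_array(panel_or_dosages: HaplotypePanel | np.ndarray) -> np.ndarray:
    if isinstance(panel_or_dosages, HaplotypePanel):
        return panel_or_dosages.dosages().values.astype(float)
    return np.asarray(panel_or_dosages, dtype=float)


def pair_qtls(
    panel_or_dosages: HaplotypePanel | np.ndarray,
    qtl_a: np.ndarray,
    target_r: float,
    window_snps: int = 50,
    tolerance: float = 0.05,
    seed: int | np.random.Generator = 0,
    chrom_bounds: list[tuple[int, int]] | None = None,
    max_resample: int = 200,
) -> QTLPairSet:
    """Match each trait-A QTL with a partner locus at the LD target.

    Within ``window_snps`` of each QTL (staying inside the chromosome),
    the non-QTL locus whose signed dosage correlation with the QTL is
    closest to ``target_r`` and within ``tolerance`` of it becomes the
    trait-B partner.  QTLs with no admissible partner are resampled from
    the unused segregating loci; after ``max_resample`` failures a
    :class:`PairingError` is raised.
    """
    if not 0.0 < target_r < 1.0:
        raise ValueError("target_r must lie in (0, 1)")
    if window_snps < 1:
        raise ValueError("window_snps must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = _dosage_array(panel_or_dosages)
    n, m = d.shape
    sd = d.std(axis=0)
    centered = d - d.mean(axis=0)
    norm = np.where(sd > 0, sd * np.sqrt(n), 1.0)
    z = centered / norm  # unit-norm columns; z_i . z_j = r_ij

    if chrom_bounds is None:
        if isinstance(panel_or_dosages, HaplotypePanel):
            chrom_bounds = [
                (sl.start, sl.stop) for sl in panel_or_dosages.chrom_slices().values()
            ]
        else:
            chrom_bounds = [(0, m)]
    bound_of = np.empty((m, 2), dtype=int)
    for lo, hi in chrom_bounds:
        bound_of[lo:hi, 0] = lo
        bound_of[lo:hi, 1] = hi

    used = np.zeros(m, dtype=bool)
    used[qtl_a] = True
    segregating = sd > 0
    pool = list(np.flatnonzero(segregating & ~used))
    rng.shuffle(pool)

    out_a, out_b, out_r = [], [], []
    failures = 0
    queue = list(qtl_a)
    while queue:
        q = queue.pop()
        lo = max(bound_of[q, 0], q - window_snps)
        hi = min(bound_of[q, 1], q + window_snps + 1)
        cand = np.arange(lo, hi)
        cand = cand[(cand != q) & ~used[cand] & segregating[cand]]
        if cand.size:
            r = z[:, cand].T @ z[:, q]
            k = np.argmin(np.abs(r - target_r))
            if abs(r[k] - target_r) <= tolerance:
                b = int(cand[k])
                used[b] = True
                out_a.append(int(q))
                out_b.append(b)
                out_r.append(float(r[k]))
                continue
        # no admissible partner: resample this QTL from the unused pool
        used[q] = False
        failures += 1
        if failures > max_resample or not pool:
            raise PairingError(
                f"could not find partners at LD target {target_r} "
                f"(tolerance {tolerance}) after {failures} resampling attempts"
            )
        q_new = None
        while pool:
            cand_q = pool.pop()
            if not used[cand_q]:
                q_new = cand_q
                break
        if q_new is None:
            raise PairingError(
                f"QTL resampling pool exhausted at LD target {target_r}"
            )
        used[q_new] = True
        queue.append(q_new)

    order = np.argsort(out_a)
    return QTLPairSet(
        qtl_a=np.array(out_a)[order],
        qtl_b=np.array(out_b)[order],
        target_r=target_r,
        realized_r=np.array(out_r)[order],
    )


def sample_effects(
    n_qtl: int,
    shape: float = 0.4,
    scale: float = 2.0 / 3.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Signed QTL effects: gamma(shape, scale) magnitudes, random signs."""
    if shape <= 0 or scale <= 0:
        raise ValueError("gamma shape and scale must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    magnitude = rng.gamma(shape, scale, size=n_qtl)
    sign = rng.choice([-1.0, 1.0], size=n_qtl)
    return magnitude * sign


def compute_tbv(
    dosages: np.ndarray, qtl_indices: np.ndarray, effects: np.ndarray
) -> np.ndarray:
    """True breeding values: effects times QTL dosages, summed per individual."""
    d = np.asarray(dosages, dtype=float)
    idx = np.asarray(qtl_indices, dtype=int)
    eff = np.asarray(effects, dtype=float)
    if idx.shape != eff.shape:
        raise ValueError("qtl_indices and effects must align")
    if idx.size and (idx.min() < 0 or idx.max() >= d.shape[1]):
        raise IndexError("QTL index out of range")
    return d[:, idx] @ eff


def residual_variance(v_g: float, h2: float) -> float:
    """Residual variance from additive variance: V_e = V_g (1 - h2) / h2."""
    if v_g <= 0:
        raise ValueError("v_g must be positive")
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must lie in (0, 1)")
    return v_g * (1.0 - h2) / h2


def simulate_trait_pair(
    panel: HaplotypePanel,
    spec_a: TraitSpec,
    spec_b: TraitSpec,
    target_r: float,
    seed: int | np.random.SeedSequence = 0,
    window_snps: int = 50,
    tolerance: float = 0.05,
    variance_rows: np.ndarray | None = None,
) -> tuple[TraitData, TraitData, QTLPairSet]:
    """Run the full pipeline for one correlated trait pair.

    TBVs are computed for every individual in ``panel`` (so unphenotyped
    candidates still have TBVs for accuracy evaluation).  The additive
    variance that calibrates V_e is the empirical TBV variance over
    ``variance_rows`` (default: all rows), which lets the caller pin the
    heritability to the founder/reference population.
    """
    if spec_a.n_qtl != spec_b.n_qtl:
        raise ValueError("the two traits of a pair share QTL pairs; n_qtl must match")
    rng = np.random.default_rng(seed)
    d = _dosage_array(panel)
    rows = np.arange(d.shape[0]) if variance_rows is None else np.asarray(variance_rows)

    qtl_a = sample_qtls(d, spec_a.n_qtl, rng)
    chrom_bounds = [(sl.start, sl.stop) for sl in panel.chrom_slices().values()]
    pairs = pair_qtls(
        d, qtl_a, target_r, window_snps=window_snps, tolerance=tolerance,
        seed=rng, chrom_bounds=chrom_bounds,
    )
    pairs.effects = sample_effects(spec_a.n_qtl, spec_a.gamma_shape, spec_a.gamma_scale, rng)

    traits = []
    for qtl, spec in ((pairs.qtl_a, spec_a), (pairs.qtl_b, spec_b)):
        tbv = compute_tbv(d, qtl, pairs.effects)
        v_g = float(tbv[rows].var())
        v_e = residual_variance(v_g, spec.h2)
        resid = rng.normal(0.0, np.sqrt(v_e), size=tbv.shape[0])
        traits.append(
            TraitData(tbv=tbv, phenotype=tbv + resid, v_g=v_g, v_e=v_e, h2=spec.h2)
        )
    return traits[0], traits[1], pairs
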