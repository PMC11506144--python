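"""Gamete formation and construction of the F1 generation.

Each gamete is a crossover mosaic of the parent's two haplotypes: the
number of crossovers per chromosome is drawn uniformly from {4, 5, 6},
crossover breakpoints are uniform on the SNP-index interval (optionally
uniform in physical bp), and the starting haplotype is chosen with
probability 1/2.  A single generation is simulated with no mutation.

The mating design fixes the sire:dam ratio (default 1:24, each dam mated
to exactly one sire) and the litter size (default 12 offspring per dam).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import HaplotypePanel

__all__ = [
    "MatingDesign",
    "Pedigree",
    "sample_crossover_count",
    "make_gamete",
    "make_design",
    "build_f1",
    "sample_candidates",
    "CROSSOVER_RANGE",
]

CROSSOVER_RANGE = (4, 6)  # crossovers per chromosome per meiosis, inclusive


@dataclass
class MatingDesign:
    """Assignment of dams to sires with a fixed litter size."""

    sires: list[str]
    dams: list[str]
    dam_to_sire: dict[str, str]
    offspring_per_dam: int = 12

    def __post_init__(self) -> None:
        if set(self.dam_to_sire) != set(self.dams):
            raise ValueError("every dam must be assigned exactly one sire")
        if not set(self.dam_to_sire.values()) <= set(self.sires):
            raise ValueError("dam assigned to an unknown sire")

    @property
    def n_offspring(self) -> int:
        return len(self.dams) * self.offspring_per_dam


@dataclass
class Pedigree:
    """offspring id -> (sire id, dam id)."""

    parents: dict[str, tuple[str, str]]

    def to_text(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("id\tsire\tdam\n")
            for oid, (s, d) in self.parents.items():
                fh.write(f"{oid}\t{s}\t{d}\n")


def sample_crossover_count(rng: np.random.Generator) -> int:
    """Number of crossovers for one chromosome, uniform on {4, 5, 6}."""
    lo, hi = CROSSOVER_RANGE
    return int(rng.integers(lo, hi + 1))


def make_gamete(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    crossover_positions: np.ndarray,
    start_on_a: bool = True,
) -> np.ndarray:
    """Build one gamete as a mosaic of two parental haplotypes.

    ``crossover_positions`` are strictly increasing SNP indices in
    [1, m-1]; the copy source switches immediately before each one.
    """
    hap_a = np.asarray(hap_a)
    hap_b = np.asarray(hap_b)
    if hap_a.shape != hap_b.shape:
        raise ValueError("parental haplotypes must have equal length")
    m = hap_a.shape[0]
    pos = np.asarray(crossover_positions, dtype=int)
    if pos.size and (pos.min() < 1 or pos.max() > m - 1):
        raise ValueError("crossover positions must lie in [1, m-1]")
    if pos.size > 1 and not (np.diff(pos) > 0).all():
        raise ValueError("crossover positions must be strictly increasing")
    source = np.zeros(m, dtype=np.int8)
    np.add.at(source, pos, 1)
    source = np.cumsum(source) % 2
    if not start_on_a:
        source = 1 - source
    return np.where(source == 0, hap_a, hap_b)


def make_design(
    founders: HaplotypePanel,
    dams_per_sire: int = 24,
    offspring_per_dam: int = 12,
    rng: np.random.Generator | None = None,
) -> MatingDesign:
    """Assign dams to sires in shuffled blocks at the given ratio."""
    rng = rng or np.random.default_rng(0)
    sires = [i for i, s in zip(founders.ids, founders.sex) if s == "M"]
    dams = [i for i, s in zip(founders.ids, founders.sex) if s == "F"]
    n_sires_used = len(dams) // dams_per_sire
    if n_sires_used < 1 or n_sires_used > len(sires):
        raise ValueError(
            f"cannot serve {len(dams)} dams at 1:{dams_per_sire} with {len(sires)} sires"
        )
    use_sires = list(rng.choice(sires, size=n_sires_used, replace=False))
    use_dams = list(rng.permutation(dams))[: n_sires_used * dams_per_sire]
    assign = {
        d: use_sires[k // dams_per_sire] for k, d in enumerate(use_dams)
    }
    return MatingDesign(
        sires=use_sires, dams=use_dams, dam_to_sire=assign, offspring_per_dam=offspring_per_dam
    )


def _distinct_positions(rng: np.random.Generator, counts: np.ndarray, m: int) -> np.ndarray:
    """(n, 6) matrix of sorted crossover indices, sentinel m for unused slots."""
    n = counts.shape[0]
    hi = CROSSOVER_RANGE[1]
    pos = rng.integers(1, m, size=(n, hi))
    pos[np.arange(hi)[None, :] >= counts[:, None]] = m  # mask unused slots
    pos.sort(axis=1)
    # resample rows where active breakpoints collide (rare)
    for _ in range(100):
        dup = (np.diff(pos, axis=1) == 0) & (pos[:, 1:] < m)
        bad = dup.any(axis=1)
        if not bad.any():
            break
        k = int(bad.sum())
        repl = rng.integers(1, m, size=(k, hi))
        repl[np.arange(hi)[None, :] >= counts[bad, None]] = m
        repl.sort(axis=1)
        pos[bad] = repl
    return pos


def _gametes(
    rng: np.random.Generator, parents: HaplotypePanel, parent_rows: np.ndarray,
    chrom_slices: dict[str, slice], bp_uniform: bool = False,
) -> np.ndarray:
    """One gamete per entry of parent_rows, built chromosome by chromosome."""
    n = parent_rows.shape[0]
    m_total = parents.n_snps
    out = np.empty((n, m_total), dtype=np.uint8)
    bp = np.array([v.bp for v in parents.variants])
    h0 = np.ascontiguousarray(parents.haplotypes[:, 0, :])[parent_rows]
    h1 = np.ascontiguousarray(parents.haplotypes[:, 1, :])[parent_rows]
    for sl in chrom_slices.values():
        m = sl.stop - sl.start
        counts = rng.integers(CROSSOVER_RANGE[0], CROSSOVER_RANGE[1] + 1, size=n)
        switch = np.zeros((n, m + 1), dtype=np.uint8)
        if bp_uniform:
            # draw breakpoints uniform in physical position, map to SNP rank;
            # coinciding breakpoints cancel pairwise, hence the bincount
            cbp = bp[sl]
            hi = CROSSOVER_RANGE[1]
            raw = rng.uniform(cbp[0], cbp[-1], size=(n, hi))
            pos = np.searchsorted(cbp, raw).clip(1, m - 1)
            pos[np.arange(hi)[None, :] >= counts[:, None]] = m
            flat = (np.arange(n)[:, None] * (m + 1) + pos).ravel()
            switch = (
                np.bincount(flat, minlength=n * (m + 1)).reshape(n, m + 1).astype(np.uint8)
            )
        else:
            pos = _distinct_positions(rng, counts, m)
            # active positions are distinct within a row; only the sentinel
            # column m can repeat and it is sliced off below
            switch[np.repeat(np.arange(n), pos.shape[1]), pos.ravel()] = 1
        source = np.cumsum(switch[:, :m], axis=1, dtype=np.uint8)
        source += rng.integers(0, 2, size=n, dtype=np.uint8)[:, None]
        source &= 1
        a = h0[:, sl]
        b = h1[:, sl]
        out[:, sl] = a ^ (source & (a ^ b))
    return out


def build_f1(
    founders: HaplotypePanel,
    design: MatingDesign,
    seed: int | np.random.SeedSequence = 0,
    bp_uniform: bool = False,
) -> tuple[HaplotypePanel, Pedigree]:
    """Mate founders per the design; each offspring is one paternal plus
    one maternal gamete per chromosome, with independent crossover draws."""
    rng = np.random.default_rng(seed)
    row_of = {iid: k for k, iid in enumerate(founders.ids)}
    for pid in list(design.sires) + list(design.dams):
        if pid not in row_of:
            raise ValueError(f"design references unknown parent {pid!r}")
    sire_rows, dam_rows, names, parent_pairs = [], [], [], {}
    for d in design.dams:
        s = design.dam_to_sire[d]
        for k in range(design.offspring_per_dam):
            oid = f"O_{d}_{k + 1}"
            names.append(oid)
            parent_pairs[oid] = (s, d)
            sire_rows.append(row_of[s])
            dam_rows.append(row_of[d])
    sire_rows = np.array(sire_rows)
    dam_rows = np.array(dam_rows)
    slices = founders.chrom_slices()
    paternal = _gametes(rng, founders, sire_rows, slices, bp_uniform)
    maternal = _gametes(rng, founders, dam_rows, slices, bp_uniform)
    hap = np.stack([paternal, maternal], axis=1)
    sex = np.where(rng.random(len(names)) < 0.5, "M", "F")
    panel = HaplotypePanel(ids=names, sex=sex, haplotypes=hap, variants=list(founders.variants))
    return panel, Pedigree(parents=parent_pairs)


def sample_candidates(
    f1_panel: HaplotypePanel, n: int = 2000, seed: int | np.random.SeedSequence = 0
) -> list[str]:
    """Uniform sample of candidate ids from the F1, without replacement."""
    if n > f1_panel.n_individuals:
        raise ValueError(f"cannot sample {n} candidates from {f1_panel.n_individuals} F1")
    rng = np.random.default_rng(seed)
    rows = rng.choice(f1_panel.n_individuals, size=n, replace=False)
    return [f1_panel.ids[i] for i in np.sort(rows)]
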