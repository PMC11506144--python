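"""Scenario orchestration: simulate, fit both models, score accuracy.

Scenario 1 crosses equal-heritability trait pairs (h2 in {0.1, 0.3, 0.5})
with genetic correlations {0.2, 0.5, 0.8} and a grid of reference
population sizes; scenario 2 uses unequal-heritability pairs at a single
reference size.  Each replicate builds a founder population mated 1:24
(sire:dam) with 12 offspring per dam, samples candidates from the F1,
simulates the trait pair, fits the single-trait model per trait and the
bivariate model, and scores prediction accuracy as the squared Pearson
correlation between candidate GEBVs and TBVs.

Seeding: the master seed spawns one child per (scenario cell, reference
size, replicate) through `numpy.random.SeedSequence`, so any single
replicate can be re-run in isolation and full runs are byte-for-byte
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import HaplotypePanel, simulate_founders
from .grm import compute_grm
from .meiosis import MatingDesign, build_f1, sample_candidates
from .models import BivariateGBLUP, SingleTraitGBLUP
from .phenosim import TraitSpec, simulate_trait_pair

__all__ = ["ScenarioConfig", "accuracy", "run_scenario1", "run_scenario2", "summarize"]


def accuracy(pbv: np.ndarray, tbv: np.ndarray, squared: bool = True) -> float:
    """Prediction accuracy of candidate breeding values.

    The headline metric is the squared Pearson correlation (coefficient
    of determination) between predicted and true breeding values; set
    ``squared=False`` for the plain correlation.
    """
    pbv = np.asarray(pbv, dtype=float)
    tbv = np.asarray(tbv, dtype=float)
    if pbv.shape != tbv.shape:
        raise ValueError("pbv and tbv must have equal length")
    if pbv.std() == 0 or tbv.std() == 0:
        raise ValueError("accuracy undefined: zero variance in pbv or tbv")
    r = float(np.corrcoef(pbv, tbv)[0, 1])
    return r * r if squared else r


@dataclass
class ScenarioConfig:
    """All knobs of a scenario run; defaults give a desk-scale experiment."""

    h2_levels: tuple[float, ...] = (0.1, 0.3, 0.5)
    rg_levels: tuple[float, ...] = (0.2, 0.5, 0.8)
    ref_sizes: tuple[int, ...] = (600,)
    h2_pairs: tuple[tuple[float, float], ...] = ((0.3, 0.5), (0.1, 0.5))  # scenario 2
    n_replicates: int = 5
    n_candidates: int = 500
    n_qtl: int = 500
    dams_per_sire: int = 24
    offspring_per_dam: int = 12
    n_chrom: int = 3
    snps_per_chrom: int = 1000
    chrom_length_bp: int = 100_000_000
    adjacency_rho: float = 0.95
    maf_low: float = 0.05
    pairing_window: int = 50
    pairing_tolerance: float = 0.05
    squared_accuracy: bool = True
    reml_tol: float = 1e-6
    reml_max_iter: int = 200
    master_seed: int = 2024

    def validate(self) -> None:
        block = self.dams_per_sire + 1
        for n_ref in self.ref_sizes:
            if n_ref % block != 0 or n_ref < block:
                raise ValueError(
                    f"reference size {n_ref} infeasible: must be a positive "
                    f"multiple of {block} (1 sire per {self.dams_per_sire} dams)"
                )
            n_dams = n_ref * self.dams_per_sire // block
            if self.n_candidates > n_dams * self.offspring_per_dam:
                raise ValueError(
                    f"cannot sample {self.n_candidates} candidates from "
                    f"{n_dams * self.offspring_per_dam} F1 offspring at n_ref={n_ref}"
                )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("h2_levels", "rg_levels", "ref_sizes"):
            if key in d:
                d[key] = tuple(d[key])
        if "h2_pairs" in d:
            d["h2_pairs"] = tuple(tuple(p) for p in d["h2_pairs"])
        return cls(**d)


def _concat_panels(a: HaplotypePanel, b: HaplotypePanel) -> HaplotypePanel:
    return HaplotypePanel(
        ids=list(a.ids) + list(b.ids),
        sex=np.concatenate([a.sex, b.sex]),
        haplotypes=np.concatenate([a.haplotypes, b.haplotypes], axis=0),
        variants=list(a.variants),
    )


def _replicate_cell(
    cfg: ScenarioConfig,
    h2_pair: tuple[float, float],
    rg: float,
    n_ref: int,
    seed: np.random.SeedSequence,
) -> list[dict]:
    """Simulate one replicate of one cell and fit all three models."""
    s_founders, s_design, s_f1, s_cand, s_traits = seed.spawn(5)
    block = cfg.dams_per_sire + 1
    pool_size = max(cfg.ref_sizes)
    founders = simulate_founders(
        pool_size,
        n_chrom=cfg.n_chrom,
        snps_per_chrom=cfg.snps_per_chrom,
        chrom_length_bp=cfg.chrom_length_bp,
        adjacency_rho=cfg.adjacency_rho,
        maf_low=cfg.maf_low,
        seed=s_founders,
        males_per_female=1.0 / cfg.dams_per_sire,
    )
    # subsample the founder pool to n_ref preserving the 1:24 ratio, then
    # rebuild the design and regenerate the F1 for this reference size
    rng = np.random.default_rng(s_design)
    males = np.flatnonzero(founders.sex == "M")
    females = np.flatnonzero(founders.sex == "F")
    n_sires = n_ref // block
    n_dams = n_ref - n_sires
    if n_sires > males.size or n_dams > females.size:
        raise ValueError(f"founder pool too small for reference size {n_ref}")
    keep = np.sort(
        np.concatenate(
            [
                rng.choice(males, size=n_sires, replace=False),
                rng.choice(females, size=n_dams, replace=False),
            ]
        )
    )
    ref_panel = founders.subset(keep)
    sires = [i for i, s in zip(ref_panel.ids, ref_panel.sex) if s == "M"]
    dams = [i for i, s in zip(ref_panel.ids, ref_panel.sex) if s == "F"]
    assign = {d: sires[k // cfg.dams_per_sire] for k, d in enumerate(rng.permutation(dams))}
    design = MatingDesign(
        sires=sires, dams=dams, dam_to_sire=assign, offspring_per_dam=cfg.offspring_per_dam
    )

    f1, _ = build_f1(ref_panel, design, seed=s_f1)
    cand_ids = sample_candidates(f1, n=cfg.n_candidates, seed=s_cand)
    f1_row = {iid: k for k, iid in enumerate(f1.ids)}
    cand_rows = [f1_row[i] for i in cand_ids]
    cand_panel = f1.subset(np.array(cand_rows))
    combined = _concat_panels(ref_panel, cand_panel)

    spec_a = TraitSpec(h2=h2_pair[0], n_qtl=cfg.n_qtl)
    spec_b = TraitSpec(h2=h2_pair[1], n_qtl=cfg.n_qtl)
    trait_a, trait_b, _pairs = simulate_trait_pair(
        combined,
        spec_a,
        spec_b,
        target_r=rg,
        seed=s_traits,
        window_snps=cfg.pairing_window,
        tolerance=cfg.pairing_tolerance,
        variance_rows=np.arange(ref_panel.n_individuals),
    )

    grm = compute_grm(combined.dosages())
    ref_ids = list(ref_panel.ids)
    ref_slice = slice(0, ref_panel.n_individuals)
    cand_slice = slice(ref_panel.n_individuals, combined.n_individuals)

    rows: list[dict] = []

    def record(model, trait_idx, res):
        trait = (trait_a, trait_b)[trait_idx]
        gebv = (
            res.gebv(cand_ids)
            if model == "single"
            else res.gebv(trait_idx, cand_ids)
        )
        acc = accuracy(gebv, trait.tbv[cand_slice], squared=cfg.squared_accuracy)
        row = {
            "model": model,
            "trait": trait_idx + 1,
            "accuracy": acc,
            "h2_true": trait.h2,
            "converged": res.converged,
            "status": res.convergence.status,
            "n_iter": res.convergence.n_iter,
            "seconds_reml": res.timings.get("reml", np.nan),
            "seconds_blup": res.timings.get("blup", np.nan),
        }
        if model == "single":
            row["h2_hat"] = res.varcomp.h2
            row["rg_hat"] = np.nan
        else:
            row["h2_hat"] = res.varcomp.h2(trait_idx)
            row["rg_hat"] = res.varcomp.genetic_correlation
        rows.append(row)

    for k, trait in enumerate((trait_a, trait_b)):
        res = SingleTraitGBLUP(trait.phenotype[ref_slice], ref_ids, grm).fit(
            tol=cfg.reml_tol, max_iter=cfg.reml_max_iter
        )
        record("single", k, res)
    res2 = BivariateGBLUP(
        trait_a.phenotype[ref_slice], trait_b.phenotype[ref_slice], ref_ids, grm
    ).fit(tol=cfg.reml_tol, max_iter=cfg.reml_max_iter)
    for k in range(2):
        record("multi", k, res2)
    return rows


def _run_grid(
    cfg: ScenarioConfig,
    pairs: list[tuple[float, float]],
    progress: bool = False,
) -> pd.DataFrame:
    cfg.validate()
    root = np.random.SeedSequence(cfg.master_seed)
    all_rows = []
    cells = [(pair, rg) for pair in pairs for rg in cfg.rg_levels]
    for ci, (pair, rg) in enumerate(cells):
        for si, n_ref in enumerate(cfg.ref_sizes):
            for rep in range(cfg.n_replicates):
                seed = np.random.SeedSequence(
                    entropy=cfg.master_seed, spawn_key=(ci, si, rep)
                )
                rows = _replicate_cell(cfg, pair, rg, n_ref, seed)
                for r in rows:
                    r.update(
                        {
                            "cell": f"h{pair[0]:g}/{pair[1]:g}_rg{rg:g}",
                            "h2_1": pair[0],
                            "h2_2": pair[1],
                            "rg": rg,
                            "n_ref": n_ref,
                            "replicate": rep,
                        }
                    )
                all_rows.extend(rows)
        if progress:
            print(f"  cell {ci + 1}/{len(cells)} done", flush=True)
    cols = [
        "cell", "h2_1", "h2_2", "rg", "n_ref", "replicate", "model", "trait",
        "accuracy", "h2_true", "h2_hat", "rg_hat", "converged", "status",
        "n_iter", "seconds_reml", "seconds_blup",
    ]
    return pd.DataFrame(all_rows)[cols]


def run_scenario1(cfg: ScenarioConfig, progress: bool = False) -> pd.DataFrame:
    """Equal-heritability grid across reference sizes (tidy per-trait rows)."""
    pairs = [(h2, h2) for h2 in cfg.h2_levels]
    return _run_grid(cfg, pairs, progress=progress)


def run_scenario2(cfg: ScenarioConfig, progress: bool = False) -> pd.DataFrame:
    """Unequal-heritability pairs at the configured reference size(s)."""
    return _run_grid(cfg, list(cfg.h2_pairs), progress=progress)


def summarize(results: pd.DataFrame, average_traits: bool = False) -> pd.DataFrame:
    """Mean/sd accuracy per cell per model plus the multi-minus-single gain.

    ``average_traits=True`` first averages the two traits within each
    replicate (scenario-1 style); otherwise traits are summarized
    separately (scenario-2 style).
    """
    df = results.copy()
    group = ["cell", "h2_1", "h2_2", "rg", "n_ref", "model"]
    if average_traits:
        df = (
            df.groupby(group + ["replicate"], as_index=False)
            .agg(accuracy=("accuracy", "mean"), converged=("converged", "all"))
        )
        df["trait"] = 0
    group = group + ["trait"]
    agg = df.groupby(group, as_index=False).agg(
        mean_accuracy=("accuracy", "mean"),
        sd_accuracy=("accuracy", lambda x: x.std(ddof=1) if len(x) > 1 else 0.0),
        n_replicates=("accuracy", "size"),
        n_nonconverged=("converged", lambda x: int((~x.astype(bool)).sum())),
    )
    wide = agg.pivot_table(
        index=[c for c in group if c != "model"],
        columns="model",
        values="mean_accuracy",
    ).reset_index()
    if {"single", "multi"} <= set(wide.columns):
        wide["improvement"] = wide["multi"] - wide["single"]
        agg = agg.merge(
            wide[[c for c in group if c != "model"] + ["improvement"]],
            on=[c for c in group if c != "model"],
            how="left",
        )
    return agg
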