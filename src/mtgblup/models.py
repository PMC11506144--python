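"""Model/Results interface for single-trait and bivariate GBLUP.

`SingleTraitGBLUP` and `BivariateGBLUP` are built from a phenotype
vector (or pair) and a GRM covering both the phenotyped reference
individuals and the unphenotyped candidates.  `fit()` runs AI-REML and
returns a results object holding the variance components with
approximate standard errors (inverse average-information), the fixed
mean(s), GEBVs for every individual in the GRM, the convergence log and
a `summary()` table.

Candidates receive GEBVs through the marginal BLUP identity
g_hat = Cov(g, y) V^{-1} (y - X b_hat), which coincides with solving the
mixed-model equations with zero incidence rows for the unphenotyped
individuals.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grm import GRM
from .reml import (
    ConvergenceLog,
    EigenGRM,
    reml_bivariate,
    reml_single,
    unpack_bivariate,
)

__all__ = [
    "VarComp1",
    "VarComp2",
    "BLUPSolution",
    "SingleTraitGBLUP",
    "BivariateGBLUP",
    "SingleTraitResults",
    "BivariateResults",
    "fit_single",
    "fit_multi",
]


@dataclass
class VarComp1:
    """Additive and residual variance of the single-trait model."""

    sigma_a2: float
    sigma_e2: float

    @property
    def h2(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)


@dataclass
class VarComp2:
    """2x2 additive (M) and residual (R) covariance of the bivariate model."""

    m_cov: np.ndarray
    r_cov: np.ndarray

    @property
    def genetic_correlation(self) -> float:
        return float(self.m_cov[0, 1] / np.sqrt(self.m_cov[0, 0] * self.m_cov[1, 1]))

    def h2(self, trait: int) -> float:
        return float(self.m_cov[trait, trait] / (self.m_cov[trait, trait] + self.r_cov[trait, trait]))


@dataclass
class BLUPSolution:
    """Fixed mean(s) and GEBVs for every individual in the GRM."""

    mu: np.ndarray
    gebv: pd.DataFrame  # index: ids; one column per trait


def _check_ids(grm: GRM, phenotyped_ids: list[str]) -> np.ndarray:
    known = set(grm.ids)
    missing = [i for i in phenotyped_ids if i not in known]
    if missing:
        raise ValueError(f"phenotyped ids not present in GRM: {missing[:5]}...")
    return grm.rows(phenotyped_ids)


class SingleTraitGBLUP:
    """y = 1*mu + Z g + e with g ~ N(0, G sigma_a^2), e ~ N(0, I sigma_e^2)."""

    def __init__(self, y: np.ndarray, phenotyped_ids: list[str], grm: GRM):
        self.y = np.asarray(y, dtype=float)
        if self.y.ndim != 1 or self.y.shape[0] != len(phenotyped_ids):
            raise ValueError("y must be a vector aligned with phenotyped_ids")
        self.phenotyped_ids = list(phenotyped_ids)
        self.grm = grm
        self.obs_rows = _check_ids(grm, self.phenotyped_ids)
        self._eig: EigenGRM | None = None

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, grm: GRM, pheno_col: str, id_col: str = "id"
    ) -> "SingleTraitGBLUP":
        return cls(df[pheno_col].to_numpy(), df[id_col].tolist(), grm)

    @property
    def eig(self) -> EigenGRM:
        if self._eig is None:
            self._eig = EigenGRM.from_matrix(self.grm.values[np.ix_(self.obs_rows, self.obs_rows)])
        return self._eig

    def fit(
        self,
        start: tuple[float, float] | None = None,
        tol: float = 1e-8,
        max_iter: int = 200,
    ) -> "SingleTraitResults":
        t0 = time.perf_counter()
        theta, log, aux = reml_single(self.y, self.eig, start=start, tol=tol, max_iter=max_iter)
        t1 = time.perf_counter()
        vc = VarComp1(sigma_a2=float(theta[0]), sigma_e2=float(theta[1]))
        py = self.eig.u @ aux["py"]  # V^{-1}(y - X mu) in the original basis
        gebv = vc.sigma_a2 * (self.grm.values[:, self.obs_rows] @ py)
        sol = BLUPSolution(
            mu=np.atleast_1d(aux["mu"]),
            gebv=pd.DataFrame({"trait1": gebv}, index=self.grm.ids),
        )
        res = SingleTraitResults(self, vc, sol, log, aux["ai"])
        res.timings = {"reml": t1 - t0, "blup": time.perf_counter() - t1}
        return res


class SingleTraitResults:
    """REML estimates, their uncertainties and BLUPs for one trait."""

    def __init__(self, model, varcomp, blup, convergence, ai):
        self.model = model
        self.varcomp: VarComp1 = varcomp
        self.blup: BLUPSolution = blup
        self.convergence: ConvergenceLog = convergence
        self._ai = ai
        self.timings: dict[str, float] = {}

    @property
    def converged(self) -> bool:
        return self.convergence.converged

    @property
    def loglik(self) -> float:
        return self.convergence.records[-1]["loglik"] if self.convergence.records else np.nan

    @property
    def params_se(self) -> np.ndarray:
        """Approximate SEs of (sigma_a^2, sigma_e^2) from the inverse AI matrix."""
        try:
            cov = np.linalg.inv(self._ai)
            return np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            return np.full(2, np.nan)

    @property
    def h2(self) -> float:
        return self.varcomp.h2

    @property
    def h2_se(self) -> float:
        """Delta-method SE of h2 = a/(a+e)."""
        a, e = self.varcomp.sigma_a2, self.varcomp.sigma_e2
        grad = np.array([e, -a]) / (a + e) ** 2
        try:
            cov = np.linalg.inv(self._ai)
            return float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        except np.linalg.LinAlgError:
            return np.nan

    def gebv(self, ids: list[str] | None = None) -> np.ndarray:
        col = self.blup.gebv["trait1"]
        return col.to_numpy() if ids is None else col.loc[ids].to_numpy()

    def summary(self) -> str:
        vc, se = self.varcomp, self.params_se
        lines = [
            "Single-trait GBLUP (AI-REML)",
            "=" * 44,
            f"{'n phenotyped':<24}{len(self.model.phenotyped_ids):>20}",
            f"{'n in GRM':<24}{self.model.grm.n:>20}",
            f"{'status':<24}{self.convergence.status:>20}",
            f"{'iterations':<24}{self.convergence.n_iter:>20}",
            f"{'restricted logL':<24}{self.loglik:>20.4f}",
            "-" * 44,
            f"{'sigma_a^2':<16}{vc.sigma_a2:>14.4f}{se[0]:>14.4f}",
            f"{'sigma_e^2':<16}{vc.sigma_e2:>14.4f}{se[1]:>14.4f}",
            f"{'h^2':<16}{vc.h2:>14.4f}{self.h2_se:>14.4f}",
            f"{'mu':<16}{self.blup.mu[0]:>14.4f}",
        ]
        return "\n".join(lines)


class BivariateGBLUP:
    """Stacked two-trait GBLUP with g ~ N(0, G (x) M) and e ~ N(0, I (x) R).

    Both traits must be observed on the same phenotyped individuals (the
    package's breeding design: a phenotyped reference population plus
    candidates unphenotyped for both traits).
    """

    def __init__(self, y1: np.ndarray, y2: np.ndarray, phenotyped_ids: list[str], grm: GRM):
        self.y = np.column_stack([np.asarray(y1, float), np.asarray(y2, float)])
        if self.y.shape[0] != len(phenotyped_ids):
            raise ValueError("y1/y2 must align with phenotyped_ids")
        if np.isnan(self.y).any():
            raise ValueError(
                "missing phenotypes within the reference set are outside the "
                "supported design; both traits must be recorded on every "
                "reference individual"
            )
        self.phenotyped_ids = list(phenotyped_ids)
        self.grm = grm
        self.obs_rows = _check_ids(grm, self.phenotyped_ids)
        self._eig: EigenGRM | None = None

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, grm: GRM, pheno_cols: tuple[str, str], id_col: str = "id"
    ) -> "BivariateGBLUP":
        return cls(df[pheno_cols[0]].to_numpy(), df[pheno_cols[1]].to_numpy(), df[id_col].tolist(), grm)

    @property
    def eig(self) -> EigenGRM:
        if self._eig is None:
            self._eig = EigenGRM.from_matrix(self.grm.values[np.ix_(self.obs_rows, self.obs_rows)])
        return self._eig

    def fit(
        self, start: np.ndarray | None = None, tol: float = 1e-8, max_iter: int = 200
    ) -> "BivariateResults":
        t0 = time.perf_counter()
        theta, log, aux = reml_bivariate(self.y, self.eig, start=start, tol=tol, max_iter=max_iter)
        t1 = time.perf_counter()
        m_cov, r_cov = unpack_bivariate(theta)
        vc = VarComp2(m_cov=m_cov, r_cov=r_cov)
        # Py per trait in the original basis, then g_hat = (M (x) G_{.,obs}) Py
        py = self.eig.u @ aux["py"]  # (n_obs, 2)
        gw = self.grm.values[:, self.obs_rows] @ py  # (n_all, 2)
        g1 = m_cov[0, 0] * gw[:, 0] + m_cov[0, 1] * gw[:, 1]
        g2 = m_cov[1, 0] * gw[:, 0] + m_cov[1, 1] * gw[:, 1]
        sol = BLUPSolution(
            mu=np.asarray(aux["mu"]),
            gebv=pd.DataFrame({"trait1": g1, "trait2": g2}, index=self.grm.ids),
        )
        res = BivariateResults(self, vc, sol, log, aux["ai"])
        res.timings = {"reml": t1 - t0, "blup": time.perf_counter() - t1}
        return res


class BivariateResults:
    """REML estimates, uncertainties and BLUPs for a trait pair."""

    def __init__(self, model, varcomp, blup, convergence, ai):
        self.model = model
        self.varcomp: VarComp2 = varcomp
        self.blup: BLUPSolution = blup
        self.convergence: ConvergenceLog = convergence
        self._ai = ai
        self.timings: dict[str, float] = {}

    @property
    def converged(self) -> bool:
        return self.convergence.converged

    @property
    def loglik(self) -> float:
        return self.convergence.records[-1]["loglik"] if self.convergence.records else np.nan

    @property
    def genetic_correlation(self) -> float:
        return self.varcomp.genetic_correlation

    @property
    def genetic_correlation_se(self) -> float:
        """Delta-method SE of rg = m12 / sqrt(m11 m22) from the AI matrix."""
        m11, m12, m22 = (
            self.varcomp.m_cov[0, 0],
            self.varcomp.m_cov[0, 1],
            self.varcomp.m_cov[1, 1],
        )
        rg = m12 / np.sqrt(m11 * m22)
        grad = np.zeros(6)
        grad[0] = -0.5 * rg / m11
        grad[1] = 1.0 / np.sqrt(m11 * m22)
        grad[2] = -0.5 * rg / m22
        try:
            cov = np.linalg.inv(self._ai)
            return float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        except np.linalg.LinAlgError:
            return np.nan

    def gebv(self, trait: int, ids: list[str] | None = None) -> np.ndarray:
        col = self.blup.gebv[f"trait{trait + 1}"]
        return col.to_numpy() if ids is None else col.loc[ids].to_numpy()

    def summary(self) -> str:
        m, r = self.varcomp.m_cov, self.varcomp.r_cov
        lines = [
            "Bivariate GBLUP (AI-REML)",
            "=" * 52,
            f"{'n phenotyped':<24}{len(self.model.phenotyped_ids):>24}",
            f"{'n in GRM':<24}{self.model.grm.n:>24}",
            f"{'status':<24}{self.convergence.status:>24}",
            f"{'iterations':<24}{self.convergence.n_iter:>24}",
            f"{'restricted logL':<24}{self.loglik:>24.4f}",
            "-" * 52,
            f"additive M    [[{m[0, 0]:10.4f} {m[0, 1]:10.4f}]",
            f"               [{m[1, 0]:10.4f} {m[1, 1]:10.4f}]]",
            f"residual R    [[{r[0, 0]:10.4f} {r[0, 1]:10.4f}]",
            f"               [{r[1, 0]:10.4f} {r[1, 1]:10.4f}]]",
            f"{'h^2 trait 1':<24}{self.varcomp.h2(0):>24.4f}",
            f"{'h^2 trait 2':<24}{self.varcomp.h2(1):>24.4f}",
            f"{'genetic correlation':<24}{self.genetic_correlation:>24.4f}"
            f"  (se {self.genetic_correlation_se:.4f})",
        ]
        return "\n".join(lines)


def fit_single(
    y: np.ndarray,
    phenotyped_ids: list[str],
    grm: GRM,
    start: tuple[float, float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> SingleTraitResults:
    """Functional entry point for the single-trait model."""
    return SingleTraitGBLUP(y, phenotyped_ids, grm).fit(start=start, tol=tol, max_iter=max_iter)


def fit_multi(
    y1: np.ndarray,
    y2: np.ndarray,
    phenotyped_ids: list[str],
    grm: GRM,
    start: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> BivariateResults:
    """Functional entry point for the bivariate model."""
    return BivariateGBLUP(y1, y2, phenotyped_ids, grm).fit(start=start, tol=tol, max_iter=max_iter)
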