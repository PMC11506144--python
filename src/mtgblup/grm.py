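"""VanRaden method-1 genomic relationship matrix.

G = W W' / sum_j 2 p_j (1 - p_j), where column j of W is the dosage at
SNP j centered by twice the allele frequency p_j.  Frequencies are
computed from the supplied matrix itself (reference and candidates
jointly) unless given, and a small epsilon is added to the diagonal so
the matrix stays invertible under near-duplicate genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import MISSING, DosageMatrix, allele_frequencies

__all__ = ["GRM", "compute_grm", "write_grm_text"]


@dataclass
class GRM:
    """Symmetric genomic relationship matrix with its provenance."""

    values: np.ndarray
    ids: list[str]
    freqs: np.ndarray
    epsilon: float

    def __post_init__(self) -> None:
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("GRM must be square")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("ids must match matrix order")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def rows(self, ids: list[str]) -> np.ndarray:
        pos = {iid: k for k, iid in enumerate(self.ids)}
        return np.array([pos[i] for i in ids])


def compute_grm(
    dosages: DosageMatrix | np.ndarray,
    ids: list[str] | None = None,
    freqs: np.ndarray | None = None,
    epsilon: float = 1e-6,
) -> GRM:
    """Build the VanRaden method-1 GRM from a complete dosage matrix."""
    if isinstance(dosages, DosageMatrix):
        ids = list(dosages.ids) if ids is None else ids
        d = dosages.values
    else:
        d = np.asarray(dosages)
    if np.any(d == MISSING):
        raise ValueError("GRM requires complete genotypes; run QC/imputation first")
    d = d.astype(float)
    n, m = d.shape
    if n < 2:
        raise ValueError("GRM needs at least two individuals")
    if ids is None:
        ids = [str(i) for i in range(n)]
    if freqs is None:
        freqs = allele_frequencies(d)
    freqs = np.asarray(freqs, dtype=float)
    segregating = (freqs > 0) & (freqs < 1)
    if not segregating.any():
        raise ValueError("all SNPs are monomorphic; GRM undefined")
    p = freqs[segregating]
    w = d[:, segregating] - 2.0 * p
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    g = (w @ w.T) / denom
    g[np.diag_indices(n)] += epsilon
    return GRM(values=g, ids=ids, freqs=freqs, epsilon=epsilon)


def write_grm_text(grm: GRM, path: str) -> None:
    """Lower triangle as tab-separated (id_i, id_j, value) rows."""
    with open(path, "w") as fh:
        for i in range(grm.n):
            for j in range(i + 1):
                fh.write(f"{grm.ids[i]}\t{grm.ids[j]}\t{grm.values[i, j]:.6f}\n")
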