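"""Reading and writing PLINK genotype files (bed/bim/fam and ped/map).

Implements the PLINK 1.9 SNP-major binary layout: a 3-byte header
(0x6c, 0x1b, 0x01) followed by ceil(n/4) bytes per SNP, two bits per
individual packed LSB-first with codes 00 = hom A1, 01 = missing,
10 = het, 11 = hom A2.  Dosages here count the A1 (alternate) allele,
so 00 -> 2, 10 -> 1, 11 -> 0.  PLINK 1 stores unphased genotypes, so
writing a phased panel keeps dosages but discards phase.
"""

from __future__ import annotations

import os

import numpy as np

from .genome import MISSING, DosageMatrix, HaplotypePanel, VariantRecord

__all__ = ["read_plink", "write_plink", "PlinkFormatError"]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> A1 dosage
_CODE_TO_DOSE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Malformed or truncated PLINK file."""


def _as_dosage(data: DosageMatrix | HaplotypePanel) -> tuple[DosageMatrix, np.ndarray | None]:
    if isinstance(data, HaplotypePanel):
        return data.dosages(), data.sex
    return data, None


def write_plink(
    data: DosageMatrix | HaplotypePanel, prefix: str, fmt: str = "bed"
) -> None:
    """Write genotypes as ``prefix.bed/.bim/.fam`` or ``prefix.ped/.map``."""
    dm, sex = _as_dosage(data)
    if fmt == "bed":
        _write_bed(dm, sex, prefix)
    elif fmt == "ped":
        _write_ped(dm, sex, prefix)
    else:
        raise ValueError(f"unknown PLINK format {fmt!r}; use 'bed' or 'ped'")


def read_plink(prefix: str) -> DosageMatrix:
    """Read ``prefix.bed/.bim/.fam`` (preferred) or ``prefix.ped/.map``."""
    if os.path.exists(prefix + ".bed"):
        return _read_bed(prefix)
    if os.path.exists(prefix + ".ped"):
        return _read_ped(prefix)
    raise FileNotFoundError(f"no PLINK fileset at {prefix!r} (.bed or .ped)")


def _sex_codes(sex: np.ndarray | None, n: int) -> list[str]:
    if sex is None:
        return ["0"] * n
    return ["1" if s == "M" else "2" if s == "F" else "0" for s in sex]


def _write_fam(dm: DosageMatrix, sex: np.ndarray | None, path: str) -> None:
    codes = _sex_codes(sex, dm.n_individuals)
    with open(path, "w") as fh:
        for iid, s in zip(dm.ids, codes):
            fh.write(f"{iid} {iid} 0 0 {s} -9\n")


def _write_bim(variants: list[VariantRecord], path: str) -> None:
    with open(path, "w") as fh:
        for v in variants:
            fh.write(f"{v.chrom} {v.snp_id} 0 {v.bp} {v.allele_alt} {v.allele_ref}\n")


def _write_bed(dm: DosageMatrix, sex: np.ndarray | None, prefix: str) -> None:
    _write_fam(dm, sex, prefix + ".fam")
    _write_bim(dm.variants, prefix + ".bim")
    n = dm.n_individuals
    n_bytes = (n + 3) // 4
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        codes = np.empty(n, dtype=np.uint8)
        for j in range(dm.n_snps):
            col = dm.values[:, j]
            for dose, code in _DOSE_TO_CODE.items():
                codes[col == dose] = code
            packed = np.zeros(n_bytes, dtype=np.uint8)
            shifts = (np.arange(n) % 4) * 2
            np.bitwise_or.at(packed, np.arange(n) // 4, codes << shifts)
            fh.write(packed.tobytes())


def _read_fam(path: str) -> list[str]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing PLINK file {path}")
    with open(path) as fh:
        return [line.split()[1] for line in fh if line.strip()]


def _read_bim(path: str) -> list[VariantRecord]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing PLINK file {path}")
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.split()
            if not f:
                continue
            out.append(
                VariantRecord(chrom=f[0], snp_id=f[1], bp=int(f[3]), allele_alt=f[4], allele_ref=f[5])
            )
    return out


def _read_bed(prefix: str) -> DosageMatrix:
    ids = _read_fam(prefix + ".fam")
    variants = _read_bim(prefix + ".bim")
    n, m = len(ids), len(variants)
    n_bytes = (n + 3) // 4
    with open(prefix + ".bed", "rb") as fh:
        raw = fh.read()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(
            f"{prefix}.bed: bad magic bytes {raw[:3]!r}; not a SNP-major PLINK 1.9 bed file"
        )
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != n_bytes * m:
        raise PlinkFormatError(
            f"{prefix}.bed: expected {n_bytes * m} genotype bytes for {n} ind x {m} SNPs, "
            f"found {body.size}"
        )
    body = body.reshape(m, n_bytes)
    shifts = (np.arange(n) % 4) * 2
    codes = (body[:, np.arange(n) // 4] >> shifts) & 0b11
    values = _CODE_TO_DOSE[codes].T.copy()  # (n, m)
    return DosageMatrix(values=values, ids=ids, variants=variants)


def _write_ped(dm: DosageMatrix, sex: np.ndarray | None, prefix: str) -> None:
    with open(prefix + ".map", "w") as fh:
        for v in dm.variants:
            fh.write(f"{v.chrom} {v.snp_id} 0 {v.bp}\n")
    codes = _sex_codes(sex, dm.n_individuals)
    with open(prefix + ".ped", "w") as fh:
        for i, (iid, s) in enumerate(zip(dm.ids, codes)):
            fields = [iid, iid, "0", "0", s, "-9"]
            for j, v in enumerate(dm.variants):
                d = dm.values[i, j]
                if d == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [v.allele_alt] * int(d) + [v.allele_ref] * (2 - int(d))
            fh.write(" ".join(fields) + "\n")


def _read_ped(prefix: str) -> DosageMatrix:
    if not os.path.exists(prefix + ".map"):
        raise FileNotFoundError(f"missing PLINK file {prefix}.map")
    variants = []
    with open(prefix + ".map") as fh:
        for line in fh:
            f = line.split()
            if f:
                variants.append(VariantRecord(chrom=f[0], snp_id=f[1], bp=int(f[3])))
    ids, rows = [], []
    with open(prefix + ".ped") as fh:
        for line in fh:
            f = line.split()
            if not f:
                continue
            if len(f) != 6 + 2 * len(variants):
                raise PlinkFormatError(
                    f"{prefix}.ped: row for {f[1] if len(f) > 1 else '?'} has {len(f)} fields, "
                    f"expected {6 + 2 * len(variants)}"
                )
            ids.append(f[1])
            alleles = f[6:]
            row = np.empty(len(variants), dtype=np.int8)
            for j, v in enumerate(variants):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                if a == "0" or b == "0":
                    row[j] = MISSING
                else:
                    row[j] = (a == v.allele_alt) + (b == v.allele_alt)
            rows.append(row)
    # alt alleles in .map are unknown; infer from first non-ref seen is not
    # possible here, so the writer's A/B convention is assumed.
    return DosageMatrix(values=np.array(rows), ids=ids, variants=variants)
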