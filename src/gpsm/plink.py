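"""PLINK v1 bed/bim/fam reader and writer.

Dialect: SNP-major .bed (magic bytes 0x6c 0x1b 0x01); dosages count copies
of the .bim A1 allele, which is stored as ``allele_b`` in the dataset. The
2-bit codes per sample are, from the low bits of each byte upward::

    00 -> 2 copies of A1 (hom A1)
    01 -> missing
    10 -> 1 copy (het)
    11 -> 0 copies (hom A2)

The .fam FID column carries the population label and IID the sample id;
parents, sex and phenotype columns are written as unknown/missing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GenotypeData, filter_autosomes

logger = logging.getLogger(__name__)

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# code -> dosage of A1; NaN for the missing code 01
_DECODE = np.array([2.0, np.nan, 1.0, 0.0])
# dosage -> code (missing handled separately)
_ENCODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
_MISSING_CODE = 0b01


def read_plink(prefix, autosomes_only: bool = True) -> GenotypeData:
    """Read a bed/bim/fam triple into a :class:`GenotypeData`."""
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not prefix.with_suffix(ext).exists():
            raise FileNotFoundError(f"missing PLINK file: {prefix.with_suffix(ext)}")

    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos_bp", "a1", "a2"],
        dtype={"snp_id": str, "a1": str, "a2": str},
    )
    snps = pd.DataFrame(
        {
            "snp_id": bim["snp_id"],
            "chrom": pd.to_numeric(bim["chrom"], errors="coerce").fillna(-1).astype(int),
            "pos_bp": bim["pos_bp"].astype(int),
            "allele_a": bim["a2"],
            "allele_b": bim["a1"],
        }
    )

    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    samples = pd.DataFrame(
        {
            "sample_id": fam["iid"],
            "population": fam["fid"],
            "birth_month": pd.NA,
            "age_months": np.nan,
        }
    )

    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:3]) != _MAGIC:
        raise ValueError(f"{prefix.with_suffix('.bed')}: bad PLINK v1 magic bytes "
                         "(expected SNP-major 0x6c 0x1b 0x01)")
    body = raw[3:]
    bytes_per_snp = (n + 3) // 4
    if len(body) != bytes_per_snp * m:
        raise ValueError(
            f"{prefix.with_suffix('.bed')}: {len(body)} data bytes, expected "
            f"{bytes_per_snp * m} for {n} samples x {m} SNPs"
        )
    mat = body.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, low bits first
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (mat >> (2 * k)) & 0b11
    dosages = _DECODE[codes[:, :n]].T  # samples x SNPs

    ds = GenotypeData(dosages, snps, samples)
    if autosomes_only:
        ds = filter_autosomes(ds)
    return ds


def write_plink(ds: GenotypeData, prefix) -> None:
    """Write bed/bim/fam; round-trips losslessly through :func:`read_plink`."""
    if ds.n_snps == 0 or ds.n_samples == 0:
        raise ValueError("refusing to write an empty dataset")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    bim = pd.DataFrame(
        {
            "chrom": ds.snps["chrom"],
            "snp_id": ds.snps["snp_id"],
            "cm": 0,
            "pos_bp": ds.snps["pos_bp"],
            "a1": ds.snps["allele_b"],
            "a2": ds.snps["allele_a"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": ds.samples["population"].fillna("0"),
            "iid": ds.samples["sample_id"],
            "father": 0,
            "mother": 0,
            "sex": 0,
            "phenotype": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n, m = ds.n_samples, ds.n_snps
    d = ds.dosages
    codes = np.full((m, n), _MISSING_CODE, dtype=np.uint8)
    for dosage, code in _ENCODE.items():
        codes[(d == dosage).T] = code
    bad = ~(np.isnan(d) | np.isin(d, [0.0, 1.0, 2.0]))
    if bad.any():
        raise ValueError("dosages must be 0, 1, 2 or NaN to write PLINK .bed")

    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((m, pad), dtype=np.uint8)], axis=1
        )
    packed = np.zeros((m, codes.shape[1] // 4), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        packed.tofile(fh)
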