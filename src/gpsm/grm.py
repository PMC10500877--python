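"""Genomic relationship matrix (Yang et al. estimator) and its PCA.

The off-diagonal between individuals j and k averages, over SNPs non-missing
in both, the cross-product of centred, standardised dosages

    G_jk = (1/m_jk) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

while the diagonal uses the less biased estimator

    G_jj = 1 + (1/m_jj) sum_i [x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2] / (2 p_i (1 - p_i)),

with p_i the allele_b frequency computed in the analysed subset. Missing
genotypes are handled by per-pair deletion: every pairwise sum runs over the
SNPs observed in both individuals, with the pair-specific count m_jk.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .data import GenotypeData


@dataclass
class KinshipMatrix:
    """Symmetric genomic relationship matrix with per-pair SNP counts."""

    values: np.ndarray
    sample_ids: list[str]
    n_snps_used: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or len(self.sample_ids) != n:
            raise ValueError("GRM dimensions do not match sample ids")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_genotypes(cls, ds: GenotypeData) -> "KinshipMatrix":
        return make_grm(ds)

    # -- persistence: GCTA binary triple and plain text ----------------------
    def to_gcta(self, prefix) -> None:
        """Write grm.bin / grm.N.bin / grm.id (lower triangle, float32)."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        idx = np.tril_indices(self.n)
        self.values[idx].astype("<f4").tofile(f"{prefix}.grm.bin")
        self.n_snps_used[idx].astype("<f4").tofile(f"{prefix}.grm.N.bin")
        with open(f"{prefix}.grm.id", "w") as fh:
            for sid in self.sample_ids:
                fh.write(f"0\t{sid}\n")

    @classmethod
    def from_gcta(cls, prefix) -> "KinshipMatrix":
        prefix = Path(prefix)
        ids = [line.split()[1] for line in open(f"{prefix}.grm.id")]
        n = len(ids)
        tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4").astype(np.float64)
        ntri = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
        if len(tri) != n * (n + 1) // 2:
            raise ValueError("grm.bin size does not match grm.id")
        values = np.zeros((n, n))
        counts = np.zeros((n, n))
        idx = np.tril_indices(n)
        values[idx], counts[idx] = tri, ntri
        values = values + np.tril(values, -1).T
        counts = counts + np.tril(counts, -1).T
        return cls(values, ids, counts)

    def to_text(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.sample_ids,
                          columns=self.sample_ids)
        df.to_csv(path, sep="\t")

    def pca(self, k: int) -> "PcaResult":
        return pca(self, k)


def make_grm(ds: GenotypeData) -> KinshipMatrix:
    """Yang et al. GRM with per-pair deletion of missing genotypes."""
    x = ds.dosages
    n, m = x.shape
    p = ds.allele_freq()
    mono = (p <= 0.0) | (p >= 1.0) | ~np.isfinite(p)
    if mono.any():
        raise ValueError(
            f"{int(mono.sum())} monomorphic SNPs reached GRM construction; "
            "apply QC (MAF filter) first"
        )
    denom = 2.0 * p * (1.0 - p)

    obs = ~np.isnan(x)
    w = (x - 2.0 * p) / np.sqrt(denom)
    w[~obs] = 0.0

    values = w @ w.T
    counts = obs.astype(np.float64) @ obs.astype(np.float64).T
    with np.errstate(invalid="ignore", divide="ignore"):
        values /= counts

    # Yang diagonal estimator replaces the plain cross-product diagonal
    xs = np.where(obs, x, 0.0)
    diag_terms = (xs * xs - (1.0 + 2.0 * p) * xs + 2.0 * p * p) / denom
    diag_terms[~obs] = 0.0
    m_jj = obs.sum(axis=1)
    np.fill_diagonal(values, 1.0 + diag_terms.sum(axis=1) / m_jj)

    return KinshipMatrix(values, ds.samples["sample_id"].tolist(), counts)


@dataclass
class PcaResult:
    """Top-k eigenpairs of a GRM; scores are eigenvector * sqrt(eigenvalue)."""

    eigenvalues: np.ndarray
    components: np.ndarray
    sample_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.components[:, i]
                for i in range(self.components.shape[1])}
        return pd.DataFrame({"sample_id": self.sample_ids, **cols})


def pca(grm: KinshipMatrix, k: int) -> PcaResult:
    """Principal components of the GRM (GCTA-style scores)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= grm.n:
        raise ValueError(f"k={k} must be smaller than the GRM dimension {grm.n}")
    vals, vecs = linalg.eigh(grm.values)
    order = np.argsort(vals)[::-1][:k]
    vals, vecs = vals[order], vecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(k):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    scores = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return PcaResult(vals, scores, list(grm.sample_ids))
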