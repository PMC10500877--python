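"""Genotype dataset container, the AGE generation proxy, and sample/SNP filters.

The dependent variable of every analysis in this package is AGE: the number
of months between an animal's birth month and a fixed epoch (January 2006 by
default). Animals born before the epoch have negative AGE, those born during
the epoch month have AGE 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_EPOCH = "2006-01"

SNP_COLUMNS = ["snp_id", "chrom", "pos_bp", "allele_a", "allele_b"]
SAMPLE_COLUMNS = ["sample_id", "population", "birth_month", "age_months"]


def _to_period(value) -> pd.Period:
    if isinstance(value, pd.Period):
        return value.asfreq("M")
    return pd.Period(value, freq="M")


def compute_age(birth_month, epoch=DEFAULT_EPOCH) -> int:
    """Months between ``birth_month`` and ``epoch`` (positive if born after).

    Accepts 'YYYY-MM' strings, datetimes, or pandas monthly Periods; the day
    of month, when present, is ignored.
    """
    b, e = _to_period(birth_month), _to_period(epoch)
    return (b - e).n


@dataclass
class GenotypeData:
    """Sample x SNP dosage matrix with per-sample and per-SNP metadata.

    ``dosages`` holds counts of ``allele_b`` copies as float (0/1/2), with
    NaN marking missing genotypes. ``ancestry``, when present, is a
    samples x populations table of predicted breed proportions.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame
    ancestry: pd.DataFrame | None = field(default=None)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample rows vs {n} dosage rows")
        if len(self.snps) != m:
            raise ValueError(f"{len(self.snps)} SNP rows vs {m} dosage columns")
        self.snps = self.snps.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        if self.ancestry is not None:
            self.ancestry = self.ancestry.reset_index(drop=True)
            if len(self.ancestry) != n:
                raise ValueError("ancestry table length mismatch")

    # -- basic properties ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of allele_b among non-missing genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=1)

    # -- subsetting ----------------------------------------------------------
    def take(self, sample_idx=None, snp_idx=None) -> "GenotypeData":
        d = self.dosages
        samples, snps, anc = self.samples, self.snps, self.ancestry
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            d = d[sample_idx, :]
            samples = samples.iloc[sample_idx]
            anc = anc.iloc[sample_idx] if anc is not None else None
        if snp_idx is not None:
            snp_idx = np.asarray(snp_idx)
            d = d[:, snp_idx]
            snps = snps.iloc[snp_idx]
        return GenotypeData(d.copy(), snps.copy(), samples.copy(),
                            anc.copy() if anc is not None else None)

    def subset_populations(self, populations) -> "GenotypeData":
        keep = self.samples["population"].isin(list(populations)).to_numpy()
        if not keep.any():
            raise ValueError(f"no samples in populations {populations}")
        return self.take(sample_idx=np.flatnonzero(keep))


def filter_autosomes(ds: GenotypeData, autosomes=range(1, 19)) -> GenotypeData:
    """Keep only SNPs on the listed autosomes (pig: chromosomes 1-18)."""
    keep = ds.snps["chrom"].isin(list(autosomes)).to_numpy()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("autosome filter removed %d non-autosomal SNPs", dropped)
    return ds.take(snp_idx=np.flatnonzero(keep))


def qc_filter(
    ds: GenotypeData,
    snp_call_rate: float = 0.90,
    maf: float = 0.01,
    sample_call_rate: float = 0.90,
) -> tuple[GenotypeData, pd.DataFrame]:
    """Array quality control: SNP call rate, then sample call rate, then MAF.

    Thresholds are exclusive on the low side (a SNP with call rate exactly
    0.90 survives). Returns the filtered dataset and a stepwise report so
    alternative filter orders can be audited.
    """
    for name, t in (("snp_call_rate", snp_call_rate), ("maf", maf),
                    ("sample_call_rate", sample_call_rate)):
        if not 0 < t <= 1:
            raise ValueError(f"{name} threshold must be in (0, 1], got {t}")

    steps = []

    keep_snp = ds.snp_call_rate() >= snp_call_rate
    steps.append(("snp_call_rate", int((~keep_snp).sum())))
    ds = ds.take(snp_idx=np.flatnonzero(keep_snp))

    keep_sample = ds.sample_call_rate() >= sample_call_rate
    steps.append(("sample_call_rate", int((~keep_sample).sum())))
    ds = ds.take(sample_idx=np.flatnonzero(keep_sample))

    if ds.n_samples == 0 or ds.n_snps == 0:
        raise ValueError("no samples or SNPs left after call-rate filtering")

    keep_maf = ds.maf() >= maf
    steps.append(("maf", int((~keep_maf).sum())))
    ds = ds.take(snp_idx=np.flatnonzero(keep_maf))

    if ds.n_snps == 0:
        raise ValueError("no SNPs left after MAF filtering")

    report = pd.DataFrame(steps, columns=["step", "removed"])
    report["remaining_samples"] = ds.n_samples
    report["remaining_snps"] = ds.n_snps
    for step, removed in steps:
        logger.info("QC %s: removed %d", step, removed)
    return ds, report


def purity_filter(
    ds: GenotypeData,
    min_prop: float = 0.95,
    crossbred_labels: tuple[str, ...] = ("Crossbred",),
) -> GenotypeData:
    """Drop purebred samples whose predicted own-breed proportion is < min_prop.

    Crossbred samples are always retained: their deviation from expected
    breed composition cannot be told apart from Mendelian sampling noise.
    The boundary is inclusive (exactly ``min_prop`` is retained).
    """
    pops = ds.samples["population"].to_numpy()
    is_cross = np.isin(pops, list(crossbred_labels))
    keep = np.ones(ds.n_samples, dtype=bool)
    for i in np.flatnonzero(~is_cross):
        pop = pops[i]
        if ds.ancestry is None or pop not in ds.ancestry.columns or \
                pd.isna(ds.ancestry.iloc[i][pop]):
            raise ValueError(
                f"purebred sample {ds.samples['sample_id'].iloc[i]} lacks "
                f"ancestry proportion for its population {pop!r}"
            )
        keep[i] = ds.ancestry.iloc[i][pop] >= min_prop
    removed = int((~keep).sum())
    if removed:
        logger.info("purity filter removed %d purebred samples", removed)
    return ds.take(sample_idx=np.flatnonzero(keep))
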