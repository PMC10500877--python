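"""Shared fixtures: small synthetic datasets, pedigrees and gene-drops."""

import numpy as np
import pandas as pd
import pytest

import gpsm
from gpsm.data import GenotypeData


def make_dataset(n, m, seed=0, missing_rate=0.0, freqs=None, ages=None,
                 population="Sim"):
    """Random-mating dataset with binomial dosages, for unit tests."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, m) if freqs is None else np.broadcast_to(freqs, (m,))
    x = rng.binomial(2, p, size=(n, m)).astype(float)
    if missing_rate:
        x[rng.random((n, m)) < missing_rate] = np.nan
    per_chrom = max(m // 18, 1)
    chrom = np.minimum(np.arange(m) // per_chrom + 1, 18)
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{i}" for i in range(m)],
            "chrom": chrom,
            "pos_bp": (np.arange(m) % per_chrom + 1) * 100_000,
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    if ages is None:
        ages = rng.integers(60, 180, size=n).astype(float)
    birth = [str(pd.Period("2006-01") + int(a)) for a in ages]
    samples = pd.DataFrame(
        {
            "sample_id": [f"id{i}" for i in range(n)],
            "population": population,
            "birth_month": birth,
            "age_months": np.asarray(ages, dtype=float),
        }
    )
    return GenotypeData(x, snps, samples)


def drop_monomorphic(ds):
    p = ds.allele_freq()
    return ds.take(snp_idx=np.flatnonzero((p > 0) & (p < 1)))


@pytest.fixture(scope="session")
def small_drift_world():
    """One small drift pedigree with its gene-drop, shared across tests."""
    cfg = gpsm.BreedingConfig(
        n_generations=6, n_founder_sires=10, n_founder_dams=60,
        litter_size=6, dams_selected_frac=1 / 3, index_accuracy=0.0,
    )
    ped = gpsm.generate_pedigree(cfg, seed=11)
    pool = gpsm.simulate_founder_pool(400, 1800, seed=12)
    assignment = gpsm.assign_pedigree_founders(pool, ped, seed=13)
    dropped = gpsm.drop(assignment, ped, seed=14)
    return {"cfg": cfg, "ped": ped, "pool": pool,
            "assignment": assignment, "dropped": dropped}
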