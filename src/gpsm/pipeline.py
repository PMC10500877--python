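"""End-to-end orchestration: QC -> GRM -> REML -> scan -> summaries.

Every stochastic stage takes an explicit seed and replicate sub-seeds are
drawn deterministically from the run seed, so any output table is
reproducible bit-for-bit from (inputs, config, seed). A manifest recording
seeds and stage row counts is written alongside the outputs.
"""

from __future__ import annotations

import gc
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genedrop
from .data import GenotypeData, qc_filter
from .grm import KinshipMatrix
from .pedigree import Pedigree
from .reml import AgeVarianceModel, BivariateAgeModel, BivarResults
from .scan import SelectionScanModel, SelectionScanResults

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration shared by the pipeline subcommands."""

    snp_call_rate: float = 0.90
    sample_call_rate: float = 0.90
    maf: float = 0.01
    fdr_threshold: float = 0.10
    window_bp: int = 100_000
    seed: int = 0
    n_replicates: int = 5
    pool_founders: int = 5_000
    pool_sites: int = 90_000
    n_array_snps: int = 20_000
    founder_scheme: str = "method1_shared"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__annotations__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _subseeds(seed: int, k: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=k)


def run_gpsm(
    ds: GenotypeData,
    config: RunConfig | None = None,
    out_dir=None,
    apply_qc: bool = True,
) -> SelectionScanResults:
    """QC, GRM, null REML, per-SNP scan and q-values on one dataset."""
    config = config or RunConfig()
    manifest = {"stage_counts": {"input": [ds.n_samples, ds.n_snps]}}
    if apply_qc:
        ds, report = qc_filter(ds, config.snp_call_rate, config.maf,
                               config.sample_call_rate)
        manifest["qc"] = report.to_dict(orient="records")
        manifest["stage_counts"]["post_qc"] = [ds.n_samples, ds.n_snps]
    grm = KinshipMatrix.from_genotypes(ds)
    results = SelectionScanModel(ds, grm).fit(
        fdr_threshold=config.fdr_threshold)
    manifest["pve"] = results.vc.pve
    manifest["n_significant"] = results.n_significant
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        results.to_csv(out_dir / "associations.tsv")
        with open(out_dir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    return results


def run_genedrop_null(
    ped: Pedigree,
    genotyped_ids,
    config: RunConfig | None = None,
    out_dir=None,
) -> tuple[pd.DataFrame, float]:
    """Gene-drop drift null replicated and scanned end-to-end.

    For each replicate a founder pool is simulated, assigned to the pedigree
    founders, dropped through the recorded matings, reduced to a random SNP
    array over the genotyped animals, and run through the full scan with the
    real AGE values. Returns the per-replicate report and the pooled
    error rate, 100 x significant / tested (%).
    """
    config = config or RunConfig()
    seeds = _subseeds(config.seed, 3 * config.n_replicates)
    rows = []
    for r in range(config.n_replicates):
        s_pool, s_assign, s_drop = seeds[3 * r: 3 * r + 3]
        try:
            pool = genedrop.simulate_founder_pool(
                config.pool_founders, config.pool_sites, seed=int(s_pool))
            assignment = genedrop.assign_pedigree_founders(
                pool, ped, scheme="method1_shared", seed=int(s_assign))
            dropped = genedrop.drop(assignment, ped, seed=int(s_drop))
            ds = genedrop.extract_array(
                dropped, ped, genotyped_ids, config.n_array_snps,
                seed=int(s_drop), min_maf=config.maf)
            del dropped, pool, assignment
            gc.collect()
            grm = KinshipMatrix.from_genotypes(ds)
            res = SelectionScanModel(ds, grm).fit(
                fdr_threshold=config.fdr_threshold)
            rows.append(
                {
                    "replicate": r + 1,
                    "n_samples": ds.n_samples,
                    "n_snps": ds.n_snps,
                    "n_significant": res.n_significant,
                    "error_rate_pct": res.error_rate(),
                    "pve": res.vc.pve,
                    "failed": False,
                }
            )
            del ds, grm, res
            gc.collect()
        except Exception as exc:  # record and continue, per replicate
            logger.exception("replicate %d failed", r + 1)
            rows.append({"replicate": r + 1, "n_samples": 0, "n_snps": 0,
                         "n_significant": 0, "error_rate_pct": np.nan,
                         "pve": np.nan, "failed": True, "error": str(exc)})
    report = pd.DataFrame(rows)
    ok = report[~report["failed"]]
    tested = int(ok["n_snps"].sum())
    pooled = 100.0 * ok["n_significant"].sum() / tested if tested else np.nan
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_csv(out_dir / "genedrop_null.tsv", sep="\t", index=False)
        with open(out_dir / "manifest.yaml", "w") as fh:
            yaml.safe_dump({"seed": config.seed,
                            "replicate_seeds": seeds.tolist(),
                            "pooled_error_rate_pct": float(pooled)},
                           fh, sort_keys=False)
    return report, float(pooled)


def run_bivariate(
    ds: GenotypeData, populations: tuple[str, str],
    config: RunConfig | None = None,
) -> BivarResults:
    """Bivariate variance components for two populations in one dataset."""
    config = config or RunConfig()
    p1, p2 = populations
    if p1 == p2:
        raise ValueError("the two populations must differ")
    sub = ds.subset_populations([p1, p2])
    present = set(sub.samples["population"])
    missing = {p1, p2} - present
    if missing:
        raise ValueError(f"populations missing from data: {sorted(missing)}")
    grm = KinshipMatrix.from_genotypes(sub)
    y = sub.samples["age_months"].to_numpy(dtype=float)
    model = BivariateAgeModel(y, grm, sub.samples["population"].to_numpy())
    return model.fit()


def run_genedrop_bivariate(
    ped: Pedigree,
    genotyped_ids,
    populations: tuple[str, str],
    config: RunConfig | None = None,
) -> BivarResults:
    """Bivariate fit on a gene-drop null over a two-population pedigree.

    ``founder_scheme`` in the config selects the shared-pool (recently
    diverged) or independent-pool (unrelated) founder extreme.
    """
    config = config or RunConfig()
    seeds = _subseeds(config.seed, 4)
    if config.founder_scheme == "method1_shared":
        pool = genedrop.simulate_founder_pool(
            config.pool_founders, config.pool_sites, seed=int(seeds[0]))
    elif config.founder_scheme == "method2_independent":
        pool = {
            pop: genedrop.simulate_founder_pool(
                config.pool_founders, config.pool_sites, seed=int(seeds[i]))
            for i, pop in enumerate(populations)
        }
    else:
        raise ValueError(f"unknown founder scheme {config.founder_scheme!r}")
    assignment = genedrop.assign_pedigree_founders(
        pool, ped, scheme=config.founder_scheme, seed=int(seeds[2]))
    dropped = genedrop.drop(assignment, ped, seed=int(seeds[3]))
    ds = genedrop.extract_array(dropped, ped, genotyped_ids,
                                config.n_array_snps, seed=int(seeds[3]),
                                min_maf=config.maf)
    return run_bivariate(ds, populations, config)
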