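"""Synthetic multi-generation breeding programs with truncation selection.

The generator emulates the structure a selection-mapping analysis assumes:
discrete generations of litters, truncation selection of replacement sires
and dams on a polygenic index, a generation interval around 27 months, and
genotype sampling concentrated in recent birth years. Selection acts on a
single index equal to the true polygenic breeding value observed with noise;
``index_accuracy`` (the correlation between ranking criterion and true
breeding value) is the lever that turns selection from absent (0, pure
drift) to strong. Under drift the pedigree's genotypes are exchangeable with
a plain gene-drop through the same pedigree — the same meiosis engine is
used for both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import compute_age
from .genedrop import DroppedGenotypes, FounderPool, _MeiosisEngine
from .pedigree import UNKNOWN, Pedigree


@dataclass
class BreedingConfig:
    """Parameters of the simulated breeding program.

    Defaults describe a modest nucleus herd: 12 discrete generations,
    litters of 8, the top 10% of male and 25% of female candidates retained
    (which keeps the herd size stationary at one litter per dam), and a
    27-month generation interval with +/-3 months of birth jitter.
    """

    n_generations: int = 12
    n_founder_sires: int = 40
    n_founder_dams: int = 400
    litters_per_dam: int = 1
    litter_size: int = 8
    sires_selected_frac: float = 0.10
    dams_selected_frac: float = 0.25
    generation_interval_months: int = 27
    birth_month_jitter: int = 3
    founder_birth_month: str = "1993-01"
    population: str = "SimPop"
    n_causal_loci: int = 50
    causal_effect_sd: float = 1.0
    index_accuracy: float = 0.7

    def __post_init__(self):
        for name in ("sires_selected_frac", "dams_selected_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.litter_size < 1 or self.litters_per_dam < 1:
            raise ValueError("litter_size and litters_per_dam must be >= 1")
        if not 0 <= self.index_accuracy <= 1:
            raise ValueError("index_accuracy must be in [0, 1]")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")


def _birth_month(cfg: BreedingConfig, generation: int, rng) -> str:
    jitter = int(rng.integers(-cfg.birth_month_jitter,
                              cfg.birth_month_jitter + 1)) \
        if cfg.birth_month_jitter else 0
    months = generation * cfg.generation_interval_months + jitter
    period = pd.Period(cfg.founder_birth_month, freq="M") + max(months, 0)
    return str(period)


class _Breeder:
    """Generation-by-generation construction shared by drift and selection."""

    def __init__(self, cfg: BreedingConfig, seed: int):
        self.cfg = cfg
        self.rng = np.random.default_rng(seed)
        self.rows: list[dict] = []
        self.sex: dict[str, str] = {}

    def founders(self):
        cfg, rng = self.cfg, self.rng
        sires, dams = [], []
        for i in range(cfg.n_founder_sires):
            sid = f"{cfg.population}_g0_s{i}"
            self._add(sid, UNKNOWN, UNKNOWN, 0, rng)
            self.sex[sid] = "M"
            sires.append(sid)
        for i in range(cfg.n_founder_dams):
            did = f"{cfg.population}_g0_d{i}"
            self._add(did, UNKNOWN, UNKNOWN, 0, rng)
            self.sex[did] = "F"
            dams.append(did)
        return sires, dams

    def _add(self, iid, sire, dam, generation, rng):
        self.rows.append(
            {
                "id": iid,
                "sire": sire,
                "dam": dam,
                "birth_month": _birth_month(self.cfg, generation, rng),
                "population": self.cfg.population,
                "generation": generation,
            }
        )

    def litters(self, sires, dams, generation):
        """Mate every dam to a random selected sire; return offspring ids."""
        cfg, rng = self.cfg, self.rng
        offspring = []
        k = 0
        for dam in dams:
            for _ in range(cfg.litters_per_dam):
                sire = sires[int(rng.integers(len(sires)))]
                for _ in range(cfg.litter_size):
                    iid = f"{cfg.population}_g{generation}_{k}"
                    k += 1
                    self._add(iid, sire, dam, generation, rng)
                    self.sex[iid] = "M" if rng.random() < 0.5 else "F"
                    offspring.append((iid, sire, dam))
        return offspring

    def select(self, offspring, scores):
        """Truncation-select replacement sires and dams by descending score."""
        cfg = self.cfg
        ids = np.array([o[0] for o in offspring])
        males = np.array([self.sex[i] == "M" for i in ids])
        order = np.argsort(-np.asarray(scores), kind="stable")
        ranked = ids[order]
        ranked_male = males[order]
        n_s = max(1, round(cfg.sires_selected_frac * int(males.sum())))
        n_d = max(1, round(cfg.dams_selected_frac * int((~males).sum())))
        sires = ranked[ranked_male][:n_s].tolist()
        dams = ranked[~ranked_male][:n_d].tolist()
        if not sires or not dams:
            raise ValueError("selection produced no parents")
        return sires, dams

    def pedigree(self) -> Pedigree:
        return Pedigree(pd.DataFrame(self.rows))


def generate_pedigree(cfg: BreedingConfig, seed: int) -> Pedigree:
    """Drift-mode pedigree: parents chosen at random each generation."""
    b = _Breeder(cfg, seed)
    sires, dams = b.founders()
    for g in range(1, cfg.n_generations + 1):
        offspring = b.litters(sires, dams, g)
        scores = b.rng.random(len(offspring))
        sires, dams = b.select(offspring, scores)
    return b.pedigree()


@dataclass
class SelectionTruth:
    """Causal loci and effects used to rank selection candidates."""

    causal_sites: np.ndarray  # site indices into the pool site map
    effects: np.ndarray
    table: pd.DataFrame = field(repr=False)


def simulate_selection(
    cfg: BreedingConfig, pool: FounderPool, seed: int,
    truth: "SelectionTruth | None" = None,
) -> tuple[Pedigree, DroppedGenotypes, SelectionTruth]:
    """Breed under truncation selection on a noisy polygenic index.

    Every candidate's true breeding value is the dot product of its causal
    dosages with effects drawn N(0, causal_effect_sd^2); the ranking
    criterion correlates with it at ``index_accuracy``. With accuracy 0 this
    reduces exactly to drift. Genotypes are propagated by the gene-drop
    meiosis engine, so Mendelian consistency holds by construction.
    Passing an existing ``truth`` reuses its causal loci and effects, so two
    populations can be selected on the same underlying objective.
    """
    b = _Breeder(cfg, seed)
    rng = b.rng
    engine = _MeiosisEngine(pool.site_map)
    n_sites = pool.n_sites
    if cfg.n_causal_loci > n_sites:
        raise ValueError("more causal loci requested than pool sites")

    if truth is not None:
        causal, effects = truth.causal_sites, truth.effects
    else:
        causal = np.sort(rng.choice(n_sites, size=cfg.n_causal_loci,
                                    replace=False))
        effects = rng.normal(0.0, cfg.causal_effect_sd,
                             size=cfg.n_causal_loci)

    sires, dams = b.founders()
    founder_ids = sires + dams
    n_found = len(founder_ids)
    if n_found > pool.n_founders:
        raise ValueError("founder pool smaller than pedigree founder count")
    pool_idx = rng.choice(pool.n_founders, size=n_found, replace=False)

    haps = [np.empty((2 * n_found, n_sites), dtype=np.uint8)]
    ids: list[str] = list(founder_ids)
    index = {}
    for i, (fid, j) in enumerate(zip(founder_ids, pool_idx)):
        haps[0][2 * i] = pool.haplotypes[2 * j]
        haps[0][2 * i + 1] = pool.haplotypes[2 * j + 1]
        index[fid] = (0, i)

    prov = pd.DataFrame({"id": founder_ids, "pool": "selection",
                         "pool_index": pool_idx})

    def diplotype(iid):
        blk, i = index[iid]
        return haps[blk][2 * i], haps[blk][2 * i + 1]

    for g in range(1, cfg.n_generations + 1):
        offspring = b.litters(sires, dams, g)
        block = np.empty((2 * len(offspring), n_sites), dtype=np.uint8)
        blk = len(haps)
        haps.append(block)
        dos_causal = np.empty((len(offspring), len(causal)))
        for i, (iid, sire, dam) in enumerate(offspring):
            sa, sb = diplotype(sire)
            da, db = diplotype(dam)
            block[2 * i] = engine.gamete(sa, sb, rng)
            block[2 * i + 1] = engine.gamete(da, db, rng)
            index[iid] = (blk, i)
            ids.append(iid)
            dos_causal[i] = (block[2 * i, causal].astype(np.int16)
                             + block[2 * i + 1, causal])

        tbv = dos_causal @ effects
        acc = cfg.index_accuracy
        sd = tbv.std()
        z = (tbv - tbv.mean()) / sd if sd > 0 else np.zeros_like(tbv)
        scores = acc * z + np.sqrt(max(1.0 - acc**2, 0.0)) * \
            rng.standard_normal(len(offspring))
        sires, dams = b.select(offspring, scores)

    ped = b.pedigree()
    hap = np.concatenate(haps, axis=0)
    # blocks are appended in pedigree row order, so ids align with rows
    dropped = DroppedGenotypes(hap, ids, pool.site_map, prov)

    truth_table = pd.DataFrame(
        {
            "snp_id": pool.site_map["snp_id"].to_numpy()[causal],
            "chrom": pool.site_map["chrom"].to_numpy()[causal],
            "pos_bp": pool.site_map["pos_bp"].to_numpy()[causal],
            "effect": effects,
        }
    )
    return ped, dropped, SelectionTruth(causal, effects, truth_table)


def assign_genotyping(
    ped: Pedigree,
    n_genotyped: int,
    seed: int,
    scheme: str = "left_skewed",
    window_generations: int = 5,
    epoch: str = "2006-01",
) -> pd.DataFrame:
    """Sample which animals are genotyped, with recency-weighted defaults.

    Only the most recent ``window_generations`` generations are eligible,
    mirroring array platforms introduced late in a breeding program. Under
    the ``left_skewed`` scheme sampling weights grow quadratically with
    generation, so counts per birth year increase toward the present; the
    ``uniform`` scheme weights eligible animals equally.
    """
    df = ped.df
    gmax = int(df["generation"].max())
    gmin = max(gmax - window_generations + 1, 0)
    eligible = df[df["generation"] >= gmin]
    if n_genotyped > len(eligible):
        raise ValueError(
            f"n_genotyped={n_genotyped} exceeds {len(eligible)} eligible "
            "animals"
        )
    gen = eligible["generation"].to_numpy()
    if scheme == "left_skewed":
        w = (gen - gmin + 1.0) ** 2
    elif scheme == "uniform":
        w = np.ones(len(eligible))
    else:
        raise ValueError(f"unknown genotyping scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(eligible), size=n_genotyped, replace=False,
                      p=w / w.sum())
    out = eligible.iloc[np.sort(pick)][
        ["id", "population", "birth_month", "generation"]
    ].rename(columns={"id": "sample_id"}).reset_index(drop=True)
    out["age_months"] = [compute_age(b, epoch) for b in out["birth_month"]]
    return out


def terminal_cross(
    sire_line: Pedigree,
    n_offspring: int,
    seed: int,
    population: str = "Crossbred",
    interval_months: int = 12,
) -> Pedigree:
    """Commercial terminal cross with sire-side-only pedigree knowledge.

    Sires are drawn from the last generation of the given purebred pedigree;
    dams (an F1 population in practice) are recorded as unknown, so a
    gene-drop through the combined pedigree draws the maternal gamete from a
    phantom founder.
    """
    rng = np.random.default_rng(seed)
    df = sire_line.df
    gmax = int(df["generation"].max())
    sires = df[df["generation"] == gmax]
    rows = []
    for k in range(n_offspring):
        sire = sires.iloc[int(rng.integers(len(sires)))]
        bm = pd.Period(sire["birth_month"], freq="M") + interval_months + \
            int(rng.integers(0, 4))
        rows.append(
            {
                "id": f"{population}_{k}",
                "sire": sire["id"],
                "dam": UNKNOWN,
                "birth_month": str(bm),
                "population": population,
                "generation": gmax + 1,
            }
        )
    return Pedigree(pd.concat([df, pd.DataFrame(rows)], ignore_index=True))
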