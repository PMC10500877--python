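"""Gene-drop simulation: the drift null for selection mapping.

Founder haplotypes are simulated in linkage equilibrium with a U-shaped
site-frequency spectrum, assigned at random (without replacement) to the
founders of a pedigree, and dropped through the exact matings recorded in
that pedigree: at every meiosis each chromosome recombines with a Poisson
number of crossovers (no interference) and the recombined gamete is
transmitted. Because the resulting genotypes are shaped only by pedigree
structure, Mendelian segregation and recombination — never by selection —
any association between them and birth date is pure genetic drift. Running
the full scan on such output measures its false-positive rate.

Founder schemes for two-population runs:

* ``method1_shared`` — all populations' founders drawn from one pool
  (recently diverged extreme);
* ``method2_independent`` — one independently simulated pool per population
  (unrelated-populations extreme).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeData, compute_age
from .pedigree import UNKNOWN, Pedigree

DEFAULT_CHROM_LENGTH_BP = 150_000_000
N_AUTOSOMES = 18


@dataclass
class FounderPool:
    """Binary founder haplotypes at sites evenly spaced along the autosomes."""

    haplotypes: np.ndarray  # (2 * n_founders, n_sites) uint8
    site_map: pd.DataFrame  # snp_id, chrom, pos_bp

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


def _default_sfs(rng: np.random.Generator, size: int) -> np.ndarray:
    """U-shaped spectrum: Beta(0.5, 0.5) truncated to [0.01, 0.99]."""
    f = rng.beta(0.5, 0.5, size=size)
    while True:
        bad = (f < 0.01) | (f > 0.99)
        if not bad.any():
            return f
        f[bad] = rng.beta(0.5, 0.5, size=int(bad.sum()))


def simulate_founder_pool(
    n_founders: int,
    n_sites: int,
    seed: int,
    sfs=None,
    chrom_length_bp: int = DEFAULT_CHROM_LENGTH_BP,
) -> FounderPool:
    """Simulate a linkage-equilibrium founder haplotype pool.

    ``sfs`` may be a callable ``(rng, size) -> frequencies``, a scalar
    frequency, or None for the default U-shaped spectrum. Fixed sites are
    redrawn so every site segregates in the pool.
    """
    if n_sites % N_AUTOSOMES != 0:
        raise ValueError(
            f"n_sites must be divisible by {N_AUTOSOMES} for even allocation, "
            f"got {n_sites}"
        )
    rng = np.random.default_rng(seed)
    if sfs is None:
        draw = _default_sfs
    elif np.isscalar(sfs):
        draw = lambda r, size: np.full(size, float(sfs))  # noqa: E731
    else:
        draw = sfs

    per_chrom = n_sites // N_AUTOSOMES
    spacing = chrom_length_bp // (per_chrom + 1)
    pos = np.tile(spacing * np.arange(1, per_chrom + 1), N_AUTOSOMES)
    chrom = np.repeat(np.arange(1, N_AUTOSOMES + 1), per_chrom)
    site_map = pd.DataFrame(
        {
            "snp_id": [f"site_{c}_{p}" for c, p in zip(chrom, pos)],
            "chrom": chrom,
            "pos_bp": pos,
        }
    )

    freqs = draw(rng, n_sites)
    hap = (rng.random((2 * n_founders, n_sites)) < freqs).astype(np.uint8)
    for _ in range(100):
        colsum = hap.sum(axis=0)
        fixed = (colsum == 0) | (colsum == hap.shape[0])
        if not fixed.any():
            break
        k = int(fixed.sum())
        f = draw(rng, k)
        hap[:, fixed] = (rng.random((hap.shape[0], k)) < f).astype(np.uint8)
    else:
        raise RuntimeError("could not obtain segregating sites at every locus")
    return FounderPool(hap, site_map)


@dataclass
class FounderAssignment:
    """Which pool individual seeded each pedigree founder."""

    pools: dict[str, FounderPool]
    mapping: dict[str, tuple[str, int]]  # pedigree id -> (pool label, index)
    scheme: str
    with_replacement: bool


def assign_pedigree_founders(
    pool, ped: Pedigree, scheme: str = "method1_shared", seed: int = 0
) -> FounderAssignment:
    """Sample distinct pool individuals for every pedigree founder.

    ``pool`` is a single :class:`FounderPool` for ``method1_shared`` or a
    ``{population: FounderPool}`` mapping for ``method2_independent``.
    """
    rng = np.random.default_rng(seed)
    founders = ped.founders
    if scheme == "method1_shared":
        if isinstance(pool, dict):
            raise ValueError("method1_shared expects a single shared pool")
        pools = {"shared": pool}
        groups = {"shared": founders["id"].tolist()}
    elif scheme == "method2_independent":
        if not isinstance(pool, dict):
            raise ValueError(
                "method2_independent expects one pool per population")
        labels = list(pool)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                if pool[a].haplotypes.shape == pool[b].haplotypes.shape and \
                        np.array_equal(pool[a].haplotypes, pool[b].haplotypes):
                    raise ValueError(
                        f"pools for {a!r} and {b!r} are identical; independent "
                        "pools must be simulated with different seeds"
                    )
        pools = dict(pool)
        groups = {
            lab: founders.loc[founders["population"] == lab, "id"].tolist()
            for lab in labels
        }
        unknown_pop = set(founders["population"]) - set(labels)
        if unknown_pop:
            raise ValueError(f"no pool supplied for populations {unknown_pop}")
    else:
        raise ValueError(f"unknown founder scheme {scheme!r}")

    mapping: dict[str, tuple[str, int]] = {}
    replaced = False
    for lab, ids in groups.items():
        nf = pools[lab].n_founders
        if len(ids) <= nf:
            idx = rng.choice(nf, size=len(ids), replace=False)
        else:
            warnings.warn(
                f"{len(ids)} pedigree founders exceed pool size {nf}; "
                "sampling with replacement", stacklevel=2
            )
            idx = rng.choice(nf, size=len(ids), replace=True)
            replaced = True
        for pid, i in zip(ids, idx):
            mapping[pid] = (lab, int(i))
    return FounderAssignment(pools, mapping, scheme, replaced)


@dataclass
class DroppedGenotypes:
    """Diplotypes for every pedigree member plus founder provenance."""

    haplotypes: np.ndarray  # (2 * n_individuals, n_sites) uint8
    ids: list[str]  # row order; individual i owns rows 2i and 2i+1
    site_map: pd.DataFrame
    provenance: pd.DataFrame  # id, pool, pool_index (phantom parents included)

    def row(self, individual_id: str) -> int:
        return self._index[individual_id]

    def __post_init__(self):
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    def dosages(self, ids) -> np.ndarray:
        rows = np.array([self._index[str(i)] for i in ids])
        return (self.haplotypes[2 * rows].astype(np.int16)
                + self.haplotypes[2 * rows + 1]).astype(np.float64)


class _MeiosisEngine:
    """Per-chromosome Poisson recombination without interference."""

    def __init__(self, site_map: pd.DataFrame, map_morgans: float = 1.0):
        self.slices = []
        chroms = site_map["chrom"].to_numpy()
        pos = site_map["pos_bp"].to_numpy(dtype=float)
        for c in np.unique(chroms):
            sel = np.flatnonzero(chroms == c)
            lo, hi = sel[0], sel[-1] + 1
            p = pos[lo:hi]
            genpos = map_morgans * (p - p[0]) / max(p[-1] - p[0], 1.0)
            self.slices.append((slice(lo, hi), genpos, map_morgans))
        self.n_sites = len(site_map)

    def gamete(self, hap_a, hap_b, rng) -> np.ndarray:
        out = np.empty(self.n_sites, dtype=np.uint8)
        for sl, genpos, L in self.slices:
            start = rng.integers(2)
            k = rng.poisson(L)
            if k == 0:
                out[sl] = hap_a[sl] if start == 0 else hap_b[sl]
            else:
                bps = np.sort(rng.random(k)) * L
                seg = np.searchsorted(bps, genpos, side="right")
                pick = (seg + start) & 1
                out[sl] = np.where(pick == 0, hap_a[sl], hap_b[sl])
        return out


def drop(
    assignment: FounderAssignment,
    ped: Pedigree,
    seed: int,
    map_morgans: float = 1.0,
) -> DroppedGenotypes:
    """Transmit founder haplotypes through the pedigree's exact matings.

    Individuals with one unknown parent receive that parent's gamete from a
    fresh ("phantom") pool founder; those with both parents unknown must be
    covered by the assignment.
    """
    rng = np.random.default_rng(seed)
    some_pool = next(iter(assignment.pools.values()))
    engine = _MeiosisEngine(some_pool.site_map, map_morgans)
    n_sites = some_pool.n_sites

    topo = ped.topological()
    ids = topo["id"].tolist()
    index = {sid: i for i, sid in enumerate(ids)}
    hap = np.zeros((2 * len(ids), n_sites), dtype=np.uint8)

    used = {lab: set(i for l, i in assignment.mapping.values() if l == lab)
            for lab in assignment.pools}
    free = {lab: [i for i in range(p.n_founders) if i not in used[lab]]
            for lab, p in assignment.pools.items()}
    for lab in free:
        rng.shuffle(free[lab])

    prov_rows = [
        {"id": pid, "pool": lab, "pool_index": i}
        for pid, (lab, i) in assignment.mapping.items()
    ]

    def phantom_gamete(population: str) -> np.ndarray:
        lab = population if population in assignment.pools else \
            next(iter(assignment.pools))
        pool = assignment.pools[lab]
        if free[lab]:
            i = free[lab].pop()
        else:
            i = int(rng.integers(pool.n_founders))
        prov_rows.append({"id": f"phantom_{len(prov_rows)}", "pool": lab,
                          "pool_index": i})
        return engine.gamete(pool.haplotypes[2 * i],
                             pool.haplotypes[2 * i + 1], rng)

    for row in topo.itertuples(index=False):
        i = index[row.id]
        sire, dam = row.sire, row.dam
        if sire == UNKNOWN and dam == UNKNOWN:
            if row.id not in assignment.mapping:
                raise ValueError(f"founder {row.id} missing from assignment")
            lab, j = assignment.mapping[row.id]
            pool = assignment.pools[lab]
            hap[2 * i] = pool.haplotypes[2 * j]
            hap[2 * i + 1] = pool.haplotypes[2 * j + 1]
            continue
        for slot, parent in enumerate((sire, dam)):
            if parent == UNKNOWN:
                hap[2 * i + slot] = phantom_gamete(row.population)
            else:
                jp = index[parent]
                hap[2 * i + slot] = engine.gamete(hap[2 * jp],
                                                  hap[2 * jp + 1], rng)

    return DroppedGenotypes(hap, ids, some_pool.site_map,
                            pd.DataFrame(prov_rows))


def mendelian_violations(dropped: DroppedGenotypes, ped: Pedigree) -> int:
    """Count (trio, site) events where a transmitted allele matches neither
    parental allele. Zero for any internally generated drop."""
    total = 0
    for row in ped.df.itertuples(index=False):
        i = dropped.row(row.id)
        for slot, parent in enumerate((row.sire, row.dam)):
            if parent == UNKNOWN:
                continue
            j = dropped.row(parent)
            child = dropped.haplotypes[2 * i + slot]
            pa = dropped.haplotypes[2 * j]
            pb = dropped.haplotypes[2 * j + 1]
            total += int(np.sum((child != pa) & (child != pb)))
    return total


def extract_array(
    dropped: DroppedGenotypes,
    ped: Pedigree,
    genotyped_ids,
    n_array_snps: int,
    seed: int,
    min_maf: float = 0.01,
    epoch: str = "2006-01",
) -> GenotypeData:
    """Random "SNP array" over the genotyped individuals.

    Sites monomorphic in the extracted sample (and, by default, sites below
    the array MAF threshold applied to real data) are excluded before the
    uniform site draw. Birth dates and the AGE proxy come from the pedigree.
    """
    rng = np.random.default_rng(seed)
    genotyped_ids = [str(i) for i in genotyped_ids]
    dos = dropped.dosages(genotyped_ids)
    p = dos.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    eligible = np.flatnonzero((p > 0) & (p < 1) & (maf >= min_maf))
    if len(eligible) < n_array_snps:
        raise ValueError(
            f"only {len(eligible)} segregating sites available for an array "
            f"of {n_array_snps}"
        )
    chosen = np.sort(rng.choice(eligible, size=n_array_snps, replace=False))

    site_map = dropped.site_map.iloc[chosen]
    snps = pd.DataFrame(
        {
            "snp_id": site_map["snp_id"].to_numpy(),
            "chrom": site_map["chrom"].to_numpy(),
            "pos_bp": site_map["pos_bp"].to_numpy(),
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    meta = ped.df.set_index("id").loc[genotyped_ids]
    samples = pd.DataFrame(
        {
            "sample_id": genotyped_ids,
            "population": meta["population"].to_numpy(),
            "birth_month": meta["birth_month"].to_numpy(),
            "age_months": [compute_age(b, epoch) for b in meta["birth_month"]],
        }
    )
    return GenotypeData(dos[:, chosen], snps, samples)
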