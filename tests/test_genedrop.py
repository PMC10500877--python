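"""Gene-drop machinery: pools, founder schemes, Mendelian transmission."""

import numpy as np
import pandas as pd
import pytest

import gpsm
from gpsm.genedrop import (
    FounderAssignment,
    FounderPool,
    assign_pedigree_founders,
    drop,
    extract_array,
    mendelian_violations,
    simulate_founder_pool,
)
from gpsm.pedigree import Pedigree


def _trio_pedigree(n_children):
    rows = [
        {"id": "S", "sire": "", "dam": "", "birth_month": "2000-01",
         "population": "P", "generation": 0},
        {"id": "D", "sire": "", "dam": "", "birth_month": "2000-01",
         "population": "P", "generation": 0},
    ]
    for k in range(n_children):
        rows.append({"id": f"c{k}", "sire": "S", "dam": "D",
                     "birth_month": "2002-01", "population": "P",
                     "generation": 1})
    return Pedigree(pd.DataFrame(rows))


def _manual_pool(haps, per_chrom=None):
    haps = np.asarray(haps, dtype=np.uint8)
    m = haps.shape[1]
    chrom = np.repeat(np.arange(1, 19), m // 18) if per_chrom is None \
        else per_chrom
    site_map = pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(m)],
        "chrom": chrom,
        "pos_bp": np.tile(np.arange(1, m // 18 + 1) * 1000, 18),
    })
    return FounderPool(haps, site_map)


class TestFounderPool:
    def test_deterministic(self):
        a = simulate_founder_pool(50, 180, seed=42)
        b = simulate_founder_pool(50, 180, seed=42)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)

    def test_point_mass_sfs_within_binomial_bounds(self):
        pool = simulate_founder_pool(500, 180, seed=1, sfs=0.5)
        f = pool.frequencies()
        # 99% binomial bounds around 0.5 with 1000 chromosomes
        half_width = 2.58 * np.sqrt(0.25 / 1000)
        assert (np.abs(f - 0.5) < half_width + 1e-9).mean() > 0.95

    def test_even_allocation_across_autosomes(self):
        pool = simulate_founder_pool(20, 90, seed=2)
        counts = pool.site_map["chrom"].value_counts()
        assert (counts == 5).all()
        for _, grp in pool.site_map.groupby("chrom"):
            assert (np.diff(grp["pos_bp"]) > 0).all()

    def test_indivisible_sites_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            simulate_founder_pool(10, 100, seed=3)

    def test_every_site_segregates(self):
        pool = simulate_founder_pool(10, 360, seed=4)
        f = pool.frequencies()
        assert ((f > 0) & (f < 1)).all()


class TestAssignment:
    def test_founders_get_distinct_pool_individuals(self, small_drift_world):
        asg = small_drift_world["assignment"]
        pairs = list(asg.mapping.values())
        assert len(pairs) == len(set(pairs))
        assert not asg.with_replacement

    def test_method1_shares_one_pool_across_populations(self):
        ped = _trio_pedigree(2)
        pool = simulate_founder_pool(10, 36, seed=5)
        asg = assign_pedigree_founders(pool, ped, "method1_shared", seed=6)
        assert set(lab for lab, _ in asg.mapping.values()) == {"shared"}

    def test_method2_identical_pools_rejected(self):
        ped = _trio_pedigree(2)
        pool = simulate_founder_pool(10, 36, seed=7)
        with pytest.raises(ValueError, match="identical"):
            assign_pedigree_founders({"P": pool, "Q": pool}, ped,
                                     "method2_independent", seed=8)

    def test_oversubscribed_pool_warns_and_replaces(self):
        ped = _trio_pedigree(0)
        pool = simulate_founder_pool(1, 36, seed=9)
        with pytest.warns(UserWarning, match="replacement"):
            asg = assign_pedigree_founders(pool, ped, seed=10)
        assert asg.with_replacement


class TestDrop:
    def test_homozygous_parents_give_homozygous_offspring(self):
        # both parents hom-alt at every site -> children always hom-alt
        haps = np.ones((4, 36), dtype=np.uint8)
        pool = _manual_pool(haps)
        ped = _trio_pedigree(5)
        asg = FounderAssignment({"shared": pool},
                                {"S": ("shared", 0), "D": ("shared", 1)},
                                "method1_shared", False)
        dropped = drop(asg, ped, seed=11)
        kids = dropped.dosages([f"c{k}" for k in range(5)])
        np.testing.assert_array_equal(kids, 2.0)

    def test_het_by_hom_segregates_half(self):
        # sire het, dam hom-ref at one site; offspring het fraction = 0.5
        haps = np.zeros((4, 36), dtype=np.uint8)
        haps[0, :] = 1  # sire haplotype A carries the alt allele everywhere
        pool = _manual_pool(haps)
        n_kids = 556  # 556 kids x 18 independent chromosomes = 10,008 trials
        ped = _trio_pedigree(n_kids)
        asg = FounderAssignment({"shared": pool},
                                {"S": ("shared", 0), "D": ("shared", 1)},
                                "method1_shared", False)
        dropped = drop(asg, ped, seed=12)
        kids = dropped.dosages([f"c{k}" for k in range(n_kids)])
        # first site of each chromosome: independent Bernoulli(0.5) draws
        first = np.arange(0, 36, 2)
        het = (kids[:, first] == 1).mean()
        n_trials = n_kids * len(first)
        assert abs(het - 0.5) < 3 * np.sqrt(0.25 / n_trials)

    def test_no_mendelian_violations(self, small_drift_world):
        assert mendelian_violations(small_drift_world["dropped"],
                                    small_drift_world["ped"]) == 0

    def test_deterministic(self, small_drift_world):
        w = small_drift_world
        again = drop(w["assignment"], w["ped"], seed=14)
        base = drop(w["assignment"], w["ped"], seed=14)
        np.testing.assert_array_equal(again.haplotypes, base.haplotypes)

    def test_allele_frequency_conserved_across_generations(self):
        # drift only: the regression of site frequency on generation has a
        # slope distribution centred at zero
        cfg = gpsm.BreedingConfig(
            n_generations=5, n_founder_sires=12, n_founder_dams=60,
            litter_size=6, dams_selected_frac=1 / 3, index_accuracy=0.0)
        slopes = []
        for rep in range(4):
            ped = gpsm.generate_pedigree(cfg, seed=200 + rep)
            pool = simulate_founder_pool(300, 720, seed=300 + rep)
            asg = assign_pedigree_founders(pool, ped, seed=400 + rep)
            dropped = drop(asg, ped, seed=500 + rep)
            gens = ped.df["generation"].to_numpy()
            dos = dropped.dosages(ped.df["id"])
            freq_by_gen = np.array(
                [dos[gens == g].mean(axis=0) / 2 for g in range(6)])
            x = np.arange(6) - 2.5
            slopes.append((x @ freq_by_gen) / (x @ x))
        slopes = np.concatenate(slopes)
        se = slopes.std(ddof=1) / np.sqrt(slopes.size)
        assert abs(slopes.mean()) < 3 * se + 1e-4

    def test_unknown_single_parent_gets_phantom_founder(self):
        rows = pd.DataFrame([
            {"id": "S", "sire": "", "dam": "", "birth_month": "2000-01",
             "population": "P", "generation": 0},
            {"id": "X", "sire": "S", "dam": "", "birth_month": "2002-01",
             "population": "P", "generation": 1},
        ])
        ped = Pedigree(rows)
        pool = simulate_founder_pool(10, 36, seed=15)
        asg = assign_pedigree_founders(pool, ped, seed=16)
        dropped = drop(asg, ped, seed=17)
        assert (dropped.provenance["id"].str.startswith("phantom")).sum() == 1
        assert mendelian_violations(dropped, ped) == 0


class TestExtractArray:
    def test_requested_snp_count_and_determinism(self, small_drift_world):
        w = small_drift_world
        ids = w["ped"].df["id"].tolist()[:200]
        a = extract_array(w["dropped"], w["ped"], ids, 500, seed=18)
        b = extract_array(w["dropped"], w["ped"], ids, 500, seed=18)
        assert a.n_snps == 500
        assert a.snps["snp_id"].tolist() == b.snps["snp_id"].tolist()
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_founders_only_returns_assigned_diplotypes(self):
        pool = simulate_founder_pool(6, 36, seed=19)
        ped = _trio_pedigree(1)
        asg = assign_pedigree_founders(pool, ped, seed=20)
        dropped = drop(asg, ped, seed=21)
        ds = extract_array(dropped, ped, ["S", "D"], 10, seed=22,
                           min_maf=0.0)
        lab, i = asg.mapping["S"]
        expected = (pool.haplotypes[2 * i].astype(float)
                    + pool.haplotypes[2 * i + 1])
        cols = [pool.site_map["snp_id"].tolist().index(s)
                for s in ds.snps["snp_id"]]
        np.testing.assert_array_equal(ds.dosages[0], expected[cols])

    def test_insufficient_sites_error(self, small_drift_world):
        w = small_drift_world
        with pytest.raises(ValueError, match="segregating"):
            extract_array(w["dropped"], w["ped"], w["ped"].df["id"][:50],
                          10_000, seed=23)

    def test_age_copied_from_pedigree(self, small_drift_world):
        w = small_drift_world
        ids = w["ped"].df["id"].tolist()[:20]
        ds = extract_array(w["dropped"], w["ped"], ids, 100, seed=24)
        meta = w["ped"].df.set_index("id").loc[ids]
        expected = [gpsm.compute_age(b) for b in meta["birth_month"]]
        assert ds.samples["age_months"].tolist() == expected


def test_inbreeding_accumulates_under_full_sib_mating():
    # five generations of repeated full-sib mating from unrelated founders:
    # F_t = (1 + 2 F_{t-1} + F_{t-2}) / 4 with F_0 = F_1 = 0 gives
    # F_5 = 0.59375. With i.i.d. Bernoulli(0.5) founder alleles any two
    # non-IBD lineage alleles differ with probability 1/2, so expected
    # heterozygosity is exactly 0.5 (1 - F).
    rows = [
        {"id": "m0", "sire": "", "dam": "", "birth_month": "1990-01",
         "population": "P", "generation": 0},
        {"id": "f0", "sire": "", "dam": "", "birth_month": "1990-01",
         "population": "P", "generation": 0},
    ]
    for g in range(1, 6):
        for sex in ("m", "f"):
            rows.append({"id": f"{sex}{g}", "sire": f"m{g-1}",
                         "dam": f"f{g-1}", "birth_month": f"{1990+g}-01",
                         "population": "P", "generation": g})
    ped = Pedigree(pd.DataFrame(rows))

    rates = []
    for rep in range(400):
        # build the founder alleles directly as i.i.d. fair coins (no
        # conditioning on segregation, which would tilt the 0.5 factor)
        rng = np.random.default_rng(600 + rep)
        pool = _manual_pool(rng.integers(0, 2, size=(4, 90)))
        asg = assign_pedigree_founders(pool, ped, seed=700 + rep)
        dropped = drop(asg, ped, seed=800 + rep)
        kid = dropped.dosages(["m5"])[0]
        rates.append((kid == 1).mean())
    rates = np.array(rates)
    f_hat = 1 - 2 * rates.mean()
    se_f = 2 * rates.std(ddof=1) / np.sqrt(rates.size)
    assert abs(f_hat - 0.59375) < 3 * se_f
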