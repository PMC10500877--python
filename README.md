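# gpsm — generation proxy selection mapping

Detects polygenic selection in temporally sampled genotype data by running
a genome-wide association of SNP dosage on **birth date**. If a locus has
been under directional selection, its allele frequency trends over time and
genotype correlates with when an animal was born; if only drift and
pedigree structure are at work, a genomic relationship matrix (GRM) in the
model absorbs the correlation. The package is written for quantitative and
population geneticists working with livestock breeding programs (the
defaults describe pig nucleus herds: 18 autosomes, ~27-month generation
interval, 40k-SNP arrays), but nothing ties it to a species.

## The model

The generation proxy is AGE, the signed number of months between an
animal's birth month and a fixed epoch (January 2006 by default). For each
SNP *s* a mixed linear model is fitted:

```
y = mu + x_s b_s + Z g + e,     g ~ N(0, G sigma_g^2),   e ~ N(0, I sigma_e^2)
```

where `y` is AGE, `x_s` the dosage vector and `G` the Yang et al. GRM.
Variance components come from one average-information REML fit of the
no-SNP model and are then fixed, so every SNP is a generalized least
squares test under `V = G sigma_g^2 + I sigma_e^2` (Wald chi-square). The
null fit also yields `PVE = sigma_g^2 / (sigma_g^2 + sigma_e^2)`, the
share of AGE variance captured by SNPs — a readout of demographic
structure, not a heritability. P-values become Storey q-values and loci
with `q < 0.10` are called selected. A bivariate REML gives the genetic
correlation `r_G = sigma_g12 / sqrt(sigma_g1^2 sigma_g2^2)` of AGE between
two populations — positive when the same loci move concordantly in both.

The drift null is a **gene-drop**: simulated founder haplotypes are
assigned to the pedigree's founders and transmitted through the recorded
matings by Mendelian segregation and Poisson recombination. Genotypes so
produced carry the full pedigree/drift structure but no selection, so the
share of `q < 0.10` calls on them is the pipeline's false-positive rate.

## Worked example

Simulate a breeding program under strong truncation selection (top 5% of
sires ranked by a noisy polygenic index, 50 causal loci, 8 generations),
genotype 1,500 animals, and scan:

```python
import gpsm

cfg = gpsm.BreedingConfig(n_generations=8, n_founder_sires=15,
                          n_founder_dams=80, litter_size=8,
                          sires_selected_frac=0.05, index_accuracy=0.9,
                          n_causal_loci=50)
pool = gpsm.simulate_founder_pool(n_founders=1000, n_sites=9000, seed=7)
ped, dropped, truth = gpsm.simulate_selection(cfg, pool, seed=7)
genotyped = gpsm.assign_genotyping(ped, 1500, seed=7, window_generations=8)
ds = gpsm.extract_array(dropped, ped, genotyped["sample_id"], 6000, seed=7)

grm = gpsm.KinshipMatrix.from_genotypes(ds)
results = gpsm.SelectionScanModel(ds, grm).fit()
print(results.summary())
```

```
Generation proxy selection mapping
============================================
samples                       1500
SNPs tested                   6000
significant (q < 0.10)         8  (0.13% of loci)
mean |beta| significant      6.703 months/allele
PVE (null model)             0.785  (SE 0.018)
```

Reading the numbers: PVE 0.785 says birth date is largely predictable from
genome-wide relatedness — normal for a closed breeding program and the
reason the GRM must stay in the model. Eight loci beat the q < 0.10
threshold; a `beta` of, say, −11.0 months/allele means carriers of that
allele are on average born almost a year earlier — the allele is being
swept *out*. Five of the eight hits in this run are true causal loci from
`truth.table`; the rest sit elsewhere in a genome whose every locus drifts.
Run the same scan on a drift-only gene-drop of the same pedigree
(`gpsm.run_genedrop_null`) and the significant count collapses to ~0 —
that contrast is the method's whole argument.

`results.table` holds the per-SNP effects, SEs, p, q and the descriptive
allele-frequency slope per year; `results.manhattan_plot()` and
`results.qq_plot()` draw the usual pictures. `AgeVarianceModel` /
`BivariateAgeModel` expose the variance-component fits directly, each with
a `summary()`.

A CLI wraps the same pipeline for shell use:

```
gpsm simulate out/sim --seed 5
gpsm scan out/sim/genotypes out/sim/pedigree.tsv out/scan
gpsm genedrop-null out/sim/pedigree.tsv out/sim/genotyped.tsv out/null
```

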