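# divkit

Analysis toolkit for the diversity of farmer-maintained crop varieties
(landraces) sampled as *populations* — the seed lot of one named variety
grown by one farmer — across zones nested in regions, phenotyped in a common
garden and genotyped with codominant microsatellite (SSR) markers.

It is aimed at population geneticists and genetic-resources scientists
working on predominantly selfing crops (the built-in defaults describe a
durum-wheat-like survey: two regions, 4 + 6 zones, 166 populations, 30
progenies scored per population, one genotyped individual per population,
14 SSR loci, outcrossing ≈ 2%).

## What it computes

* **Morphology** — a short/tall stature threshold derived from the upper
  limit of check-variety heights (≈ 90 cm), population classes for spike
  type (BW / DW / DC / DW_DC / DW_DC_CA) and stature (S / T / S<T / S=T /
  S>T) with the *pure-with-one-outlier* and *mixed-with-≥2-each* rules, and
  variety-level categorisation with outlier populations.
* **Diversity** — per-group allele counts `N_a`, Nei's unbiased expected
  heterozygosity `H_e = n/(n-1)·(1 − Σ p_i²)`, allelic richness rarefied to
  `g` gene copies `R_s = Σ_i [1 − C(n−n_i, g)/C(n, g)]`, heterozygote and
  private-allele counts, multilocus genotype sharing, and exact Wilcoxon
  signed-rank comparisons (paired per locus) with significance letters.
* **Differentiation** — Weir–Cockerham θ (global and pairwise, permutation
  p-values), a *variety-name* F_ST where each name is treated as a
  homozygous one-locus genotype, and hierarchical AMOVA (zones nested in
  regions; allele-difference distances; F_CT, F_SC, F_ST with the three
  standard permutation schemes).
* **DAPC** — from-scratch discriminant analysis of principal components:
  allele-count PCA, K-means over K with `BIC(K) = n·ln(W_K/n) + K·ln n` and
  an elbow suggestion, a-score selection of the retained PCs, Gaussian
  membership probabilities, projection of supplementary individuals through
  the training loadings, and metagroup repeatability across replicate runs.
* **Trees** — simple-matching dissimilarity, classic and size-weighted
  neighbor-joining, locus bootstrap supports, and cluster composition
  tables.
* **Synthetic data** — a generator with hierarchical Dirichlet allele
  frequencies (ancestral → region → zone; `alpha = (1−F)/F` gives expected
  fixation index `F` at each level), founder lines reproduced under partial
  selfing, fixed modern genotypes, mixed seed lots, and a full latent truth
  record, so the entire pipeline is testable without any field data.

## Worked example

```python
from divkit.synthetic_data import SimConfig, simulate_dataset
from divkit import morphology as mo, diversity as dv, differentiation as diff

ds, panel, truth = simulate_dataset(SimConfig(seed=1))
samples = ds.drop_checks()

rule = mo.derive_stature_threshold(panel)
print(round(rule.threshold_cm, 1))          # 89.8  (max of 113 check rows)

table = dv.diversity_table(samples, samples.grouping("region"), 17)
print(table.per_group.round(3))
#          N_a    H_e    R_s  NbHet    n
# group
# R1     5.857  0.671  5.441      2   60
# R2     6.143  0.610  5.275      3  101

am = diff.amova(samples, n_perm=1000, seed=1)
print(round(am.f_ct, 3), round(am.f_sc, 3))  # 0.122 0.136
print({k: round(v, 1) for k, v in am.percentages.items()})
# {'a': 12.2, 'b': 11.9, 'c': 75.8}
```

`N_a`/`H_e`/`R_s` are per-locus means per region (R_s rarefied to 17
diploid individuals); `NbHet` counts individuals heterozygous at ≥ 1 locus
— rare, as expected under ~98% selfing.  The AMOVA says 12% of the
allele-level variance lies among regions (F_CT = 0.122, p ≈ 0.005 by 1000
permutations of whole zones among regions), 12% among zones within regions,
and 76% within zones.

The same analyses are exposed as a CLI:

```bash
divkit simulate --seed 1 --out data/
divkit diversity --geno data/genotypes.csv --group zone --rarefy-min 5 --out div.tsv
divkit amova --geno data/genotypes.csv --perms 10000 --seed 1 --out amova.json
divkit dapc --geno data/genotypes.csv --kmax 25 --seed 1 --out dapc/
divkit tree --geno data/genotypes.csv --boot 1000 --seed 1 --out tree/
divkit run --seed 1 --out full_run/      # the whole pipeline + manifest
```

## Layout

```
src/divkit/
  data_model.py       validated genotype/morphology tables, Genepop IO
  synthetic_data.py   hierarchical generator + truth record
  morphology.py       stature threshold, population & variety classes
  diversity.py        N_a / H_e / R_s / NbHet, Wilcoxon + letters
  differentiation.py  Weir-Cockerham theta, name F_ST, AMOVA
  dapc.py             PCA + K-means/BIC + discriminants + projection
  tree.py             simple matching, NJ, bootstrap, composition
  pipeline.py, cli.py orchestration and the `divkit` command
docs/methods.md       model and design notes
tests/                unit, property and acceptance tests
```
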