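# Methods

## The sampling model

The package analyses surveys of a predominantly selfing crop in which a
*population* is the seed lot of one named variety grown by one farmer, one
field per population.  Populations nest in zones (groups of nearby
villages), zones nest in regions.  Two kinds of data are carried per
population: a morphology panel (up to 30 progenies, each with a spike-type
label and a mean height) and the diploid SSR genotype of one or more
individuals.  Check varieties grown across the common garden carry
`status = check` and are excluded from all group statistics unless
explicitly requested.

## Morphological classification

Stature is split at the upper limit of the check varieties' mean-height
distribution (the checks are modern semi-dwarf varieties, so their range —
about 55–90 cm — delimits "short"); `height ≤ threshold` is short, strictly
greater is tall.  A population is *pure* for a trait when all progenies
share one type with at most one outlier **and** that type is a strict
majority (so 1 + 1 is neither pure nor mixed), and *mixed* when at least two
types each have at least two progenies.  Mixed stature populations are
banded by the frequency of short progenies: `< 0.33` → S<T, `[0.33, 0.66]`
→ S=T (closed on both ends; the original wording, "between 33 and 66%",
does not settle the endpoints, so the closed choice is documented here and
the boundary cases are tested explicitly), `> 0.66` → S>T.  Spike classes:
BW (pure bread wheat or a bread-wheat majority mixture), pure DW, pure DC,
DW_DC mixtures, DW_DC_CA mixtures; any other combination is flagged
`unclassified` rather than silently coerced.  Variety categorisation takes
the strict majority of its populations' classes and lists disagreeing
populations as outliers; without a majority the variety is "no assignment".
Majority ties break deterministically (DW < DC < CA < BW) with a warning.

## Diversity statistics

`H_e` is Nei's unbiased gene diversity `n/(n−1)·(1 − Σ p_i²)` on `n`
non-missing gene copies (the estimator choice is recorded in the table
metadata).  Allelic richness uses the exact hypergeometric rarefaction
`R_s = Σ_i [1 − C(n−n_i, g)/C(n, g)]`, reported with its `g`; groups with
fewer than `g` typed copies at a locus get `NaN` there rather than a
silently different `g`.  Group comparisons are Wilcoxon signed-rank tests
pairing the per-locus values; with ≤ 14 loci the normal approximation is
poor, so the null distribution is enumerated exactly over all `2^n` sign
patterns (average ranks for ties).  Zero differences are dropped
(Wilcoxon's original treatment); identical vectors give p = 1, and fewer
than 4 non-zero differences give an undefined p (flagged) because the exact
test cannot reach conventional levels there.  Letters are assigned by a
greedy insert-and-absorb clique cover with an expansion pass, so groups
share a letter exactly when not significantly different; ordering is
deterministic in the input order.

Multilocus genotype identity is conservative: the missingness pattern is
part of the identity, so two individuals differing only by missing calls
are *not* merged — missing is incomparable, not a wildcard.  This avoids
inflating counts of genotypes shared between groups.

## Differentiation

`wc_theta` implements the Weir–Cockerham (1984) variance-component
estimator per locus and allele, including the heterozygosity terms (which
matter even at ~2% outcrossing), with per-locus complete-case handling of
missing data; loci lacking two groups with two typed individuals are
dropped with a warning.  The multilocus estimate is `Σa / Σ(a+b+c)` over
loci and alleles.  Pairwise p-values permute individuals between the two
groups; the p-value is the plain proportion of permuted θ ≥ observed
(1000 permutations by default).  The variety-name F_ST recodes each name as
a homozygous genotype at one synthetic locus and reuses the same machinery,
quantifying how much groups differ in the varieties they host.

AMOVA uses the allele-difference distance (0/1/2 mismatches per locus as
multiset differences of the unordered genotype pairs, summed over mutually
typed loci) — not a stepwise-mutation distance, which nothing in the data
justifies.  Sums of squares follow the standard hierarchical decomposition
with unequal-size coefficients; components are reported raw *and* truncated
at zero (indices are computed from the raw values, truncation is only
flagged).  Permutation schemes: F_SC permutes individuals among zones
within regions, F_CT permutes whole zones among regions, F_ST permutes
individuals among zones regardless of region; `p = (#{perm ≥ obs}+1)/(n+1)`
with 10 000 permutations by default.  With a single region, or one zone per
region, the missing stratum is reported as undefined rather than zero.

## DAPC

Individuals are encoded as allele-count vectors (0/1/2 per allele column);
missing calls are imputed with the column mean so supplementary projection
stays well defined; PCA is an exact SVD of the centered matrix.  K is
scanned by K-means with `BIC(K) = n·ln(W_K/n) + K·ln n`.  Note this BIC
typically keeps decreasing on well-separated data — only the *shape* of
the curve is informative, which is why the number of clusters is chosen at
the elbow: the suggested K is the smallest K whose improvement to K+1 falls
below 5% of the largest improvement, and the full curve is always returned
for a visual decision.  Within-run monotonicity of `W_K` is guaranteed by
seeding each K with the best K−1 centers plus the worst-fit point.  The
retained-PC count is chosen by the a-score (observed reassignment success
minus its mean under random labels); note the a-score is bounded by
`1 − 1/K` under the null, so "high" is relative to that bound.  Linear
discriminants solve the generalized eigenproblem of between- vs
within-class scatter (ridge-regularized with a flag when the within-class
scatter is singular), scaled to unit within-class variance; membership
probabilities are a Gaussian kernel on the squared distance to centroids in
discriminant space with common covariance.  Supplementary individuals are
centered with the *training* means, passed through the training PCA and
discriminant loadings, and assigned to the nearest centroid — never
refitted; alleles unseen in training contribute zero columns.

Cluster labels are arbitrary, so run-to-run stability is measured
label-free: each replicate cluster maps to the reference metagroup holding
the plurality of its members (ties toward the larger metagroup, logged),
and the repeatability of a metagroup is the mean fraction of its
individuals whose replicate cluster maps back to it; when ≥ 90% of a
metagroup travels together into one other metagroup the replicate is
credited as a merge (flagged).  The reference-cluster → metagroup map is an
analyst input (identity by default); it is not inferred.

## Trees

The simple-matching dissimilarity is 1 minus the mean per-locus proportion
of shared alleles (0, ½, 1) over mutually typed loci; a pair with no common
typed locus is an error naming the pair.  `nj_build` implements the
Saitou–Nei agglomeration; since the original software's "weighted" NJ
update is not published, classic NJ is the default and a size-weighted
reduction (`d(u,k) = (w_i(d(i,k)−b_i) + w_j(d(j,k)−b_j))/(w_i+w_j)`) is
exposed as a documented option — the topology-level conclusions drawn from
these dendrograms are robust to the choice.  Negative branch lengths are
truncated to zero and counted.  Supports are locus-bootstrap bipartition
percentages mapped onto the reference tree (figures conventionally report
those above 40%).

## The synthetic generator

Allele frequencies follow a hierarchical Dirichlet: ancestral frequencies
per locus from a symmetric Dirichlet(0.3) (uneven, SSR-like spectra; the
default 14 loci carry 5–47 alleles), then region frequencies from
`Dirichlet(α_r · p_anc)` and zone frequencies from `Dirichlet(α_z · p_reg)`
with `α = (1−F)/F`, which makes the expected fixation index of each level
exactly `F` (defaults F_CT = 0.146, F_SC = 0.171, matching the survey the
defaults emulate).  This was chosen over a coalescent island model because
the signal of interest is frequency differentiation, not genealogy; there
is no mutation during the short simulated pedigree — diversity enters only
through founder draws.

Each traditional population starts from 20 homozygous founder lines drawn
from its zone's frequencies and reproduces for 6 generations under partial
selfing (s = 0.98): an offspring is a Mendelian self of one parent with
probability s, otherwise an outcross of two.  Founder count and pedigree
depth were set so that the equilibrium fraction of individuals heterozygous
at ≥ 1 of 14 loci lands in the 5–25% range a selfer with ~2% outcrossing
shows in practice (drift among fewer founders, or a longer pedigree, pushes
it lower).  Modern varieties are fixed multilocus genotypes (drawn once
from the ancestral pool, shared across regions) adopted with per-region
probabilities (0.215 / 0.01); mixed populations (rate 0.4, an anchor for
the roughly-half mixed seed lots such surveys report, not a calibrated
contract) are seeded from two source pools.  Spike types are emitted from
the source pool with 2% noise; heights are truncated normals — short
~ N(75, 8²) on [55, 90], tall ~ N(110, 10²) on (90, 140] — and checks are
Uniform(55, 90), so pooled heights are bimodal with the antimode at the
checks' upper limit.  Seven bread-wheat populations sit in the first
northern zone and five of their genotyped seeds are excluded from the
genetic set (166 → 161 individuals), mirroring a ploidy screen.

What the generator does **not** emulate: ongoing seed exchange/migration
between populations, linkage (loci are independent, defensible for mapped
single-locus SSRs), genotyping error and null alleles, and any explicit
variety-naming process beyond zone-local name pools.  Tests passing on this
generator therefore validate the estimators and the pipeline plumbing, not
claims about real seed systems.

## Verification strategy and problem sizes

Because the survey that motivates the defaults never deposited its
genotypes, correctness is property-based: rarefaction matches exhaustive
subsample enumeration for every count vector with ≤ 8 copies; θ and AMOVA
components match independent scalar brute-force implementations to 1e-10 on
random toys; permutation tests are calibrated on panmictic pools (pooled
empirical rejection at nominal 0.05 across 450 null tests within
[0.02, 0.10]); AMOVA F_CT recovers generating values 0.05/0.15/0.30 within
±0.04 (mean of 20 seeds at 161 × 14, traditional pools only — modern
genotypes shared across regions genuinely dilute between-region
differentiation, so they are excluded from the recovery condition); DAPC
finds the elbow at the true K = 10 on ten diverged pools of 30 and projects
held-out individuals back to their source cluster ≥ 90% with metagroup
repeatability > 0.9 across 15 replicates; NJ reproduces 50 random additive
trees exactly; and the morphology rules are checked by exhaustive
enumeration of all count vectors summing to ≤ 12 against a straight-line
transcription of the published wording.  Null calibration uses 200
permutations and 4 zones of 7 populations per seed; these sizes keep the
whole suite around a minute while leaving each check statistically
meaningful.

## Known limitations

* The Weir–Cockerham estimator at region level ignores zone substructure
  and is accordingly inflated; the hierarchical AMOVA F_CT is the right
  quantity for nested designs and is what the recovery tests check.
* With only two regions, ratio estimators of F_CT have visible per-seed
  skew; recovery claims are about means over seeds.
* The exact signed-rank enumeration is limited to 20 non-zero differences
  (2^n states); ample for locus-paired comparisons at ≤ 14 loci.
* `BIC(K)` values depend on the documented formula; compare shapes, not
  absolute values, across software.
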