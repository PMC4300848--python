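"""Synthetic genotype + morphology generator for a selfing SSR-typed crop.

The generator emulates the structure of a two-region landrace survey:
zones nested in regions, farmer populations nested in zones, 30 progenies
scored per population and one genotyped individual per population.  Neutral
differentiation is produced by a hierarchical Dirichlet model of allele
frequencies (ancestral -> region -> zone): frequencies at each level are
drawn from ``Dirichlet(alpha * parent)`` with ``alpha = (1 - F) / F``, which
makes the expected fixation index of that level exactly ``F``.  Populations
are founded by homozygous multilocus lines drawn from their zone's
frequencies and then reproduced for a few generations under partial selfing,
so residual heterozygosity decays geometrically as in a real selfer.

Modern varieties are single fixed multilocus genotypes adopted with a
per-region probability; mixed populations are seeded from two source pools,
reproducing the spike-type and stature mixtures seen in farmer seed lots.
Every latent variable is kept in a :class:`TruthRecord` for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from divkit.data_model import MISSING, GenotypeDataset, MorphPanel

# Default per-locus allele counts: the 14 SSR loci of the study design span
# 5 to 47 alleles per locus.
DEFAULT_ALLELE_COUNTS = (9, 42, 5, 19, 15, 19, 47, 16, 17, 26, 23, 39, 26, 32)
DEFAULT_LOCI = tuple(f"SSR{i + 1:02d}" for i in range(14))

# Table-1-style sampling design: 4 northern and 6 southern zones.
DEFAULT_POPS_PER_ZONE = ((18, 10, 32, 5), (15, 22, 27, 8, 6, 23))


def _f_to_conc(f: float) -> float:
    if not 0 < f < 1:
        raise ValueError("target fixation index must be in (0, 1)")
    return (1.0 - f) / f


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    n_regions: int = 2
    zones_per_region: tuple[int, ...] = (4, 6)
    populations_per_zone: tuple[tuple[int, ...], ...] | None = DEFAULT_POPS_PER_ZONE
    progenies_per_population: int = 30
    individuals_per_population: int = 1

    # loci
    n_loci: int = 14
    allele_count_range: tuple[int, int] = (5, 47)
    ancestral_alpha: float = 0.3  # symmetric Dirichlet for ancestral frequencies

    # divergence: Dirichlet concentrations, parameterised by target F values
    target_fct: float = 0.146
    target_fsc: float = 0.171

    # mating & pedigree
    selfing: float = 0.98
    n_founder_lines: int = 20
    n_generations: int = 6

    # modern pools and mixtures
    n_modern_pools: int = 2
    modern_adoption: tuple[float, ...] = (0.215, 0.01)
    modern_contamination: float = 0.05
    mixture_rate: float = 0.4

    # morphology model
    dc_pool_prob: float | tuple[tuple[float, ...], ...] = 0.35
    spike_emission_noise: float = 0.02
    short_height: tuple[float, float] = (75.0, 8.0)   # mean, sd; trunc [55, 90]
    tall_height: tuple[float, float] = (110.0, 10.0)  # mean, sd; trunc (90, 140]
    check_height_range: tuple[float, float] = (55.0, 90.0)
    check_rows: tuple[int, ...] = (74, 39)
    check_names: tuple[str, ...] = ("Karim", "Marzak")

    # bread-wheat contaminant populations (placed in the first northern zone)
    n_bw_populations: int = 7
    n_bw_pure: int = 2
    n_bw_excluded: int = 5  # genotyped seeds that turn out hexaploid -> dropped

    varieties_per_zone: int = 4

    def __post_init__(self) -> None:
        for p in (self.selfing, self.mixture_rate, self.spike_emission_noise,
                  self.modern_contamination, *self.modern_adoption):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        lo, hi = self.allele_count_range
        if not (2 <= lo <= hi <= 60):
            raise ValueError("allele count range must lie within [2, 60]")
        if len(self.zones_per_region) != self.n_regions:
            raise ValueError("zones_per_region length != n_regions")
        if len(self.modern_adoption) != self.n_regions:
            raise ValueError("modern_adoption length != n_regions")
        if self.populations_per_zone is not None:
            if tuple(len(z) for z in self.populations_per_zone) != tuple(self.zones_per_region):
                raise ValueError("populations_per_zone inconsistent with zones_per_region")

    @property
    def conc_region(self) -> float:
        return _f_to_conc(self.target_fct)

    @property
    def conc_zone(self) -> float:
        return _f_to_conc(self.target_fsc)

    def zone_ids(self) -> list[tuple[str, str]]:
        """(region, zone) pairs, northern region first."""
        out = []
        for r in range(self.n_regions):
            rid = f"R{r + 1}"
            for z in range(self.zones_per_region[r]):
                out.append((rid, f"{rid}Z{z + 1}"))
        return out

    def pops_for_zone(self, r: int, z: int) -> int:
        if self.populations_per_zone is None:
            return 10
        return self.populations_per_zone[r][z]


@dataclass
class TruthRecord:
    """Every latent variable of one simulated dataset."""

    config: SimConfig
    freqs: dict                      # locus -> {"ancestral", "region", "zone"} tables
    allele_sizes: dict               # locus -> array of allele bp sizes
    populations: pd.DataFrame        # per-population latent descriptors
    progeny_truth: pd.DataFrame      # per-progeny source pool / spike / stature
    n_alleles_realized: dict         # locus -> distinct alleles in genotype output
    het_individuals: list            # genotyped individuals heterozygous at >=1 locus


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def _dirichlet_child(parent: np.ndarray, conc: float, rng: np.random.Generator) -> np.ndarray:
    """Draw Dirichlet(conc * parent); conc = inf copies the parent."""
    if not math.isfinite(conc):
        return parent.copy()
    alpha = np.maximum(conc * parent, 1e-9)
    p = rng.dirichlet(alpha)
    s = p.sum()
    return p / s


def draw_allele_frequencies(cfg: SimConfig, rng: np.random.Generator | None = None) -> tuple[dict, dict]:
    """Hierarchical frequency tables (ancestral -> region -> zone) per locus.

    Returns ``(freqs, allele_sizes)``; every frequency vector sums to 1
    within 1e-12.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    if cfg.n_loci == len(DEFAULT_ALLELE_COUNTS) and cfg.allele_count_range == (5, 47):
        n_alleles = list(DEFAULT_ALLELE_COUNTS)
    else:
        lo, hi = cfg.allele_count_range
        n_alleles = [int(rng.integers(lo, hi + 1)) for _ in range(cfg.n_loci)]
    loci = [f"SSR{i + 1:02d}" for i in range(cfg.n_loci)]
    freqs: dict = {}
    sizes: dict = {}
    for locus, k in zip(loci, n_alleles):
        sizes[locus] = 100 + 2 * np.arange(k)  # bp sizes, 2-bp repeat ladder
        anc = rng.dirichlet(np.full(k, cfg.ancestral_alpha) + 1e-6)
        anc = anc / anc.sum()
        regions = {}
        zones = {}
        for r in range(cfg.n_regions):
            rid = f"R{r + 1}"
            pr = _dirichlet_child(anc, cfg.conc_region, rng)
            regions[rid] = pr
            for z in range(cfg.zones_per_region[r]):
                zones[f"{rid}Z{z + 1}"] = _dirichlet_child(pr, cfg.conc_zone, rng)
        freqs[locus] = {"ancestral": anc, "region": regions, "zone": zones}
    return freqs, sizes


# ---------------------------------------------------------------------------
# population pools and pedigree
# ---------------------------------------------------------------------------

def _draw_lines(n: int, zone_freqs: list[np.ndarray], sizes: list[np.ndarray],
                rng: np.random.Generator) -> np.ndarray:
    """``n`` homozygous multilocus founder lines, shape (n, L, 2)."""
    L = len(zone_freqs)
    lines = np.empty((n, L, 2), dtype=np.int32)
    for j, (p, sz) in enumerate(zip(zone_freqs, sizes)):
        a = sz[rng.choice(len(p), size=n, p=p)]
        lines[:, j, 0] = a
        lines[:, j, 1] = a
    return lines


def _draw_line(zone_freqs: list[np.ndarray], sizes: list[np.ndarray],
               rng: np.random.Generator) -> np.ndarray:
    return _draw_lines(1, zone_freqs, sizes, rng)[0]


def _mate(lines: np.ndarray, n_off: int, selfing: float,
          rng: np.random.Generator) -> np.ndarray:
    """``n_off`` offspring of a line stack (n, L, 2) under partial selfing."""
    n, L, _ = lines.shape
    p1 = rng.integers(n, size=n_off)
    outcross = (rng.random(n_off) >= selfing) & (n > 1)
    p2 = np.where(outcross, rng.integers(n, size=n_off), p1)
    # one gamete from each parent; selfing means p2 == p1 (two independent
    # draws from the same parent's pair, i.e. Mendelian selfing)
    g1 = np.take_along_axis(lines[p1], rng.integers(0, 2, size=(n_off, L, 1)), axis=2)
    g2 = np.take_along_axis(lines[p2], rng.integers(0, 2, size=(n_off, L, 1)), axis=2)
    return np.concatenate([g1, g2], axis=2)


def _reproduce(lines: np.ndarray, selfing: float, n_gen: int,
               rng: np.random.Generator) -> np.ndarray:
    """Evolve a stack of lines (n, L, 2) under partial selfing."""
    for _ in range(n_gen):
        lines = _mate(lines, lines.shape[0], selfing, rng)
    return lines


def _spike_emission(pool_spike: str, noise: float) -> dict[str, float]:
    others = [t for t in ("DW", "DC", "CA") if t != pool_spike]
    em = {pool_spike: 1.0 - noise}
    if pool_spike == "BW":
        em = {"BW": 1.0 - noise}
        others = ["DW", "DC"]
    for t in others:
        em[t] = noise / len(others)
    return em


# ---------------------------------------------------------------------------
# main simulation
# ---------------------------------------------------------------------------

def simulate_dataset(cfg: SimConfig) -> tuple[GenotypeDataset, MorphPanel, TruthRecord]:
    """Simulate genotypes, morphology and the full latent truth.

    Per population, progenies descend from its source pool(s): with
    probability ``selfing`` an offspring is a selfed draw of one parental
    line, otherwise an outcross of two.  Modern-pool populations replicate a
    fixed genotype plus rare contamination.  Same seed, same bytes.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_freq, rng_pool, rng_geno, rng_morph = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    freqs, sizes = draw_allele_frequencies(cfg, rng_freq)
    loci = list(freqs)
    size_list = [sizes[l] for l in loci]

    if cfg.n_modern_pools == 0 and any(p > 0 for p in cfg.modern_adoption):
        raise ValueError(
            "infeasible config: modern adoption requested but no modern pool defined"
        )

    # fixed modern genotypes: drawn once from the ancestral pool
    anc_freqs = [freqs[l]["ancestral"] for l in loci]
    modern_genotypes = [
        _draw_line(anc_freqs, size_list, rng_pool) for _ in range(cfg.n_modern_pools)
    ]
    modern_names = [f"Modern{k + 1}" for k in range(cfg.n_modern_pools)]

    pop_rows, progeny_rows, geno_meta, geno_calls = [], [], [], []
    pop_no = 0

    for r in range(cfg.n_regions):
        rid = f"R{r + 1}"
        for z in range(cfg.zones_per_region[r]):
            zid = f"{rid}Z{z + 1}"
            zfreqs = [freqs[l]["zone"][zid] for l in loci]
            if isinstance(cfg.dc_pool_prob, (int, float)):
                dc_p = float(cfg.dc_pool_prob)
            else:
                dc_p = float(cfg.dc_pool_prob[r][z])
            # zone-local traditional variety catalogue: name -> spike type
            varieties = {
                f"{zid}_var{v + 1}": ("DC" if rng_pool.random() < dc_p else "DW")
                for v in range(cfg.varieties_per_zone)
            }
            vnames = list(varieties)
            n_pops = cfg.pops_for_zone(r, z)
            is_first_zone = (r == 0 and z == 0)
            for q in range(n_pops):
                pop_no += 1
                pid = f"P{pop_no:03d}"
                is_bw = is_first_zone and q < cfg.n_bw_populations
                is_modern = (not is_bw) and rng_pool.random() < cfg.modern_adoption[r]
                if is_modern:
                    k = int(rng_pool.integers(cfg.n_modern_pools))
                    variety, status = modern_names[k], "modern"
                    pools = [{"spike": "DW", "stature": "S", "modern": k}]
                else:
                    variety = vnames[int(rng_pool.integers(len(vnames)))]
                    status = "traditional"
                    spike = "BW" if is_bw else varieties[variety]
                    pools = [{"spike": spike, "stature": "T" if not is_bw else "T",
                              "modern": None}]
                pure_bw = is_bw and q < cfg.n_bw_pure
                mixed = (
                    not pure_bw
                    and cfg.n_founder_lines >= 2
                    and rng_pool.random() < cfg.mixture_rate
                )
                if mixed:
                    # second source pool: another variety of the zone, a modern
                    # pool, or (rarely, northern mixtures) a CA component
                    u = rng_pool.random()
                    if u < 0.2 and cfg.n_modern_pools:
                        k = int(rng_pool.integers(cfg.n_modern_pools))
                        pools.append({"spike": "DW", "stature": "S", "modern": k})
                    elif u < 0.3 and is_first_zone:
                        pools.append({"spike": "CA", "stature": "T", "modern": None})
                    else:
                        other = vnames[int(rng_pool.integers(len(vnames)))]
                        pools.append({"spike": varieties[other],
                                      "stature": "T", "modern": None})
                    mix_prop = float(rng_pool.uniform(0.25, 0.75))
                else:
                    mix_prop = 1.0

                # founder lines per pool
                n_lines = cfg.n_founder_lines
                n1 = max(1, round(mix_prop * n_lines)) if mixed else n_lines
                n1 = min(n1, n_lines - 1) if mixed else n1
                counts = [n1, n_lines - n1] if mixed else [n_lines]
                lines_parts = []
                for pool, cnt in zip(pools, counts):
                    if pool["modern"] is not None:
                        part = np.repeat(
                            modern_genotypes[pool["modern"]][None], cnt, axis=0
                        ).copy()
                        contam = rng_geno.random(cnt) < cfg.modern_contamination
                        if contam.any():
                            part[contam] = _draw_lines(
                                int(contam.sum()), zfreqs, size_list, rng_geno
                            )
                    else:
                        part = _draw_lines(cnt, zfreqs, size_list, rng_geno)
                    lines_parts.append(part)
                lines = np.concatenate(lines_parts)
                lines = _reproduce(lines, cfg.selfing, cfg.n_generations, rng_geno)

                # genotyped individual(s): one more reproduction event each
                g_ind = _mate(lines, cfg.individuals_per_population, cfg.selfing, rng_geno)
                for i_ind in range(cfg.individuals_per_population):
                    iid = pid if cfg.individuals_per_population == 1 else f"{pid}_{i_ind + 1}"
                    geno_meta.append((iid, rid, zid, pid, variety, status))
                    geno_calls.append(np.sort(g_ind[i_ind], axis=1))

                # per-progeny latent truth (morphology emitted later)
                for s in range(cfg.progenies_per_population):
                    pool_ix = 0 if (not mixed) or rng_morph.random() < mix_prop else 1
                    pool = pools[pool_ix]
                    em = _spike_emission(pool["spike"], cfg.spike_emission_noise)
                    types, probs = zip(*em.items())
                    spike = str(rng_morph.choice(types, p=np.asarray(probs) / sum(probs)))
                    progeny_rows.append(
                        (pid, f"{pid}_s{s + 1:02d}", pool_ix, spike, pool["stature"])
                    )
                pop_rows.append({
                    "population": pid, "region": rid, "zone": zid,
                    "variety": variety, "status": status, "is_mixture": mixed,
                    "is_bw": is_bw, "mix_prop": mix_prop,
                    "pool_spikes": tuple(p["spike"] for p in pools),
                    "pool_statures": tuple(p["stature"] for p in pools),
                })

    populations = pd.DataFrame(pop_rows).set_index("population")
    progeny_truth = pd.DataFrame(
        progeny_rows,
        columns=["population", "progeny", "pool", "true_spike", "true_stature"],
    )

    # hexaploid exclusions: genotyped seeds of the first n_bw_excluded BW
    # populations fail the ploidy screen and never enter the genetic set
    excluded = set(populations.index[populations["is_bw"]][: cfg.n_bw_excluded])
    keep = [i for i, m in enumerate(geno_meta) if m[3] not in excluded]
    geno_meta = [geno_meta[i] for i in keep]
    calls = np.stack([geno_calls[i] for i in keep])
    meta = pd.DataFrame(
        geno_meta, columns=["id", "region", "zone", "population", "variety", "status"]
    ).set_index("id")
    ds = GenotypeDataset(meta, loci, calls)

    panel = simulate_morphology_from_truth(progeny_truth, cfg, rng_morph)

    het = (calls[:, :, 0] != calls[:, :, 1]).any(axis=1)
    truth = TruthRecord(
        config=cfg,
        freqs=freqs,
        allele_sizes=sizes,
        populations=populations,
        progeny_truth=progeny_truth,
        n_alleles_realized={
            l: len(set(calls[:, j, :].ravel()) - {MISSING}) for j, l in enumerate(loci)
        },
        het_individuals=list(meta.index[het]),
    )
    return ds, panel, truth


def _trunc_normal(mean: float, sd: float, lo: float, hi: float,
                  rng: np.random.Generator) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x <= hi:
            return float(x)
    return float(np.clip(mean, lo + 1e-6, hi))


def simulate_morphology_from_truth(progeny_truth: pd.DataFrame, cfg: SimConfig,
                                   rng: np.random.Generator) -> MorphPanel:
    """Emit heights for the latent truth and append check rows.

    Short statures ~ Normal(75, 8^2) truncated to [55, 90]; tall ~
    Normal(110, 10^2) truncated to (90, 140]; checks ~ Uniform(55, 90), so a
    pooled height histogram is bimodal with the antimode near the checks'
    upper limit.
    """
    sm, ssd = cfg.short_height
    tm, tsd = cfg.tall_height
    rows = []
    for rec in progeny_truth.itertuples(index=False):
        if rec.true_stature == "S":
            h = _trunc_normal(sm, ssd, 55.0, 90.0, rng)
        else:
            h = _trunc_normal(tm, tsd, 90.0, 140.0, rng)
        rows.append((rec.population, rec.progeny, rec.true_spike, h, False))
    lo, hi = cfg.check_height_range
    for name, n in zip(cfg.check_names, cfg.check_rows):
        for k in range(n):
            rows.append((name, f"{name}_{k + 1:03d}", "DW",
                         float(rng.uniform(lo, hi)), True))
    df = pd.DataFrame(
        rows, columns=["population", "progeny", "spike_type", "height_cm", "is_check"]
    )
    return MorphPanel(df)


def simulate_morphology(truth: TruthRecord, cfg: SimConfig | None = None,
                        seed: int | None = None) -> MorphPanel:
    """Re-emit a morphology panel from a truth record (fresh emission noise)."""
    cfg = cfg or truth.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    return simulate_morphology_from_truth(truth.progeny_truth, cfg, rng)


def ziz_gradient_config(seed: int = 0) -> SimConfig:
    """Preset with a DC-frequency cline along the southern valley zones.

    The first three southern zones carry DC pool probabilities 0.1, 0.5 and
    0.9 so that pure-DW populations dominate the lowest zone, mixtures the
    middle one, and pure-DC the highest.
    """
    return SimConfig(
        seed=seed,
        dc_pool_prob=((0.2, 0.2, 0.4, 0.1), (0.1, 0.5, 0.9, 0.2, 0.1, 0.8)),
    )
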