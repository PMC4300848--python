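"""F-statistics and hierarchical AMOVA with permutation tests.

``wc_theta`` implements the Weir & Cockerham (1984) variance-component
estimator of F_ST for codominant diploid data, per locus and allele, with
the heterozygosity term, combined over loci as theta = sum(a) / sum(a+b+c).
``name_fst`` applies the same machinery after recoding each individual's
variety name as a homozygous genotype at one synthetic locus, quantifying
how much groups differ in the varieties they host.  ``amova`` partitions the
allele-difference distance between individuals across a two-level hierarchy
(zones nested in regions) with Excoffier-style sums of squares, unequal-size
coefficients, and the three standard permutation schemes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from divkit.data_model import MISSING, GenotypeDataset, GroupingKey


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def _locus_arrays(ds: GenotypeDataset) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per locus: (valid mask, allele-code a1, allele-code a2), codes 0..K-1."""
    out = []
    for j in range(ds.n_loci):
        a1, a2 = ds.calls[:, j, 0], ds.calls[:, j, 1]
        valid = a1 != MISSING
        alleles = np.unique(np.concatenate([a1[valid], a2[valid]]))
        lookup = {a: k for k, a in enumerate(alleles.tolist())}
        c1 = np.array([lookup.get(a, -1) for a in a1.tolist()])
        c2 = np.array([lookup.get(a, -1) for a in a2.tolist()])
        out.append((valid, c1, c2, len(alleles)))
    return out


def _wc_locus_components(valid: np.ndarray, c1: np.ndarray, c2: np.ndarray,
                         n_alleles: int, gidx: np.ndarray, n_groups: int
                         ) -> tuple[float, float, float] | None:
    """Summed (a, b, c) over alleles at one locus; None if the locus is
    unusable (fewer than 2 groups with >= 2 typed individuals) or monomorphic."""
    K = n_alleles
    g = gidx[valid]
    x1, x2 = c1[valid], c2[valid]
    n_i_all = np.bincount(g, minlength=n_groups).astype(float)
    use = n_i_all >= 2
    if use.sum() < 2 or K < 2:
        return None
    keep = use[g]
    g = g[keep]
    x1, x2 = x1[keep], x2[keep]
    # re-index the retained groups densely
    gmap = -np.ones(n_groups, dtype=int)
    gmap[np.flatnonzero(use)] = np.arange(use.sum())
    g = gmap[g]
    r = int(use.sum())
    n_i = np.bincount(g, minlength=r).astype(float)
    n_tot = n_i.sum()
    nbar = n_tot / r
    nc = (n_tot - np.sum(n_i**2) / n_tot) / (r - 1)

    copies = (
        np.bincount(g * K + x1, minlength=r * K)
        + np.bincount(g * K + x2, minlength=r * K)
    ).reshape(r, K).astype(float)
    het_mask = x1 != x2
    hcounts = (
        np.bincount(g[het_mask] * K + x1[het_mask], minlength=r * K)
        + np.bincount(g[het_mask] * K + x2[het_mask], minlength=r * K)
    ).reshape(r, K).astype(float)

    p = copies / (2.0 * n_i[:, None])          # allele freq per group
    h = hcounts / n_i[:, None]                  # het-carrier freq per group
    pbar = (n_i[:, None] * p).sum(axis=0) / n_tot
    s2 = (n_i[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i[:, None] * h).sum(axis=0) / n_tot

    if nbar <= 1:
        return None
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
    b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    c = hbar / 2.0
    return float(a.sum()), float(b.sum()), float(c.sum())


@dataclass
class ThetaResult:
    theta: float | None
    per_locus: pd.DataFrame  # locus, a, b, c
    dropped_loci: list

    def __float__(self) -> float:
        return float("nan") if self.theta is None else self.theta


def wc_theta(ds: GenotypeDataset, grouping: GroupingKey,
             loci: list[str] | None = None, warn: bool = True) -> ThetaResult:
    """Multilocus Weir-Cockerham theta with per-locus variance components.

    Loci without >= 2 groups of >= 2 typed individuals are dropped (with a
    warning); theta is None when all loci are monomorphic or dropped.
    """
    labels = grouping.labels_for(ds.individuals)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("theta needs >= 2 groups")
    gidx = np.array([groups.index(l) for l in labels])
    arrays = _locus_arrays(ds)
    locus_set = set(loci) if loci is not None else None
    rows, dropped = [], []
    for j, locus in enumerate(ds.loci):
        if locus_set is not None and locus not in locus_set:
            continue
        comp = _wc_locus_components(*arrays[j], gidx, len(groups))
        if comp is None:
            dropped.append(locus)
            continue
        rows.append({"locus": locus, "a": comp[0], "b": comp[1], "c": comp[2]})
    if dropped and warn:
        warnings.warn(f"loci dropped from theta: {dropped}")
    per_locus = pd.DataFrame(rows, columns=["locus", "a", "b", "c"])
    denom = per_locus[["a", "b", "c"]].to_numpy().sum() if len(per_locus) else 0.0
    theta = float(per_locus["a"].sum() / denom) if denom != 0.0 else None
    return ThetaResult(theta, per_locus, dropped)


def _theta_value(arrays, gidx: np.ndarray, n_groups: int) -> float | None:
    num = den = 0.0
    any_locus = False
    for valid, c1, c2, K in arrays:
        comp = _wc_locus_components(valid, c1, c2, K, gidx, n_groups)
        if comp is None:
            continue
        any_locus = True
        num += comp[0]
        den += comp[0] + comp[1] + comp[2]
    if not any_locus or den == 0.0:
        return None
    return num / den


# ---------------------------------------------------------------------------
# pairwise F_ST matrices
# ---------------------------------------------------------------------------

@dataclass
class FstMatrix:
    labels: list
    theta: pd.DataFrame
    p_values: pd.DataFrame
    mode: str = "microsatellite"
    n_perm: int = 0

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.p_values < alpha


def pairwise_fst(ds: GenotypeDataset, grouping: GroupingKey, n_perm: int = 1000,
                 seed: int | None = None, mode: str = "microsatellite") -> FstMatrix:
    """Pairwise multilocus theta with permutation p-values.

    The p-value of a pair is the plain proportion of ``n_perm`` random
    reallocations of its individuals between the two groups whose theta is
    >= the observed one; with ``n_perm=0`` p-values are absent (NaN).
    Groups of fewer than 2 individuals are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    labels = grouping.labels_for(ds.individuals)
    groups = sorted(set(labels))
    theta_m = pd.DataFrame(0.0, index=groups, columns=groups)
    p_m = pd.DataFrame(np.nan, index=groups, columns=groups)
    arrays_full = _locus_arrays(ds)
    for ga, gb in itertools.combinations(groups, 2):
        sel = np.flatnonzero((labels == ga) | (labels == gb))
        if min((labels[sel] == ga).sum(), (labels[sel] == gb).sum()) < 2:
            warnings.warn(f"pair ({ga}, {gb}) skipped: group with < 2 individuals")
            theta_m.loc[ga, gb] = theta_m.loc[gb, ga] = np.nan
            continue
        sub_arrays = [
            (valid[sel], c1[sel], c2[sel], K) for valid, c1, c2, K in arrays_full
        ]
        gidx = (labels[sel] == gb).astype(int)
        obs = _theta_value(sub_arrays, gidx, 2)
        if obs is None:
            theta_m.loc[ga, gb] = theta_m.loc[gb, ga] = np.nan
            continue
        theta_m.loc[ga, gb] = theta_m.loc[gb, ga] = obs
        if n_perm > 0:
            ge = 0
            idx = gidx.copy()
            for _ in range(n_perm):
                rng.shuffle(idx)
                t = _theta_value(sub_arrays, idx, 2)
                if t is not None and t >= obs - 1e-15:
                    ge += 1
            p_m.loc[ga, gb] = p_m.loc[gb, ga] = ge / n_perm
    return FstMatrix(groups, theta_m, p_m, mode=mode, n_perm=n_perm)


def name_dataset(ds: GenotypeDataset) -> GenotypeDataset:
    """Recode variety names as a homozygous genotype at one synthetic locus."""
    names = ds.meta["variety"].astype(str)
    if (names == "").any():
        raise ValueError("every individual needs a variety name")
    codes = {n: k + 1 for k, n in enumerate(sorted(set(names)))}
    calls = np.array([[(codes[n], codes[n])] for n in names], dtype=np.int32)
    return GenotypeDataset(ds.meta.copy(), ["variety_name"], calls)


def name_fst(ds: GenotypeDataset, grouping: GroupingKey, n_perm: int = 1000,
             seed: int | None = None) -> FstMatrix:
    """Variety-name-based F_ST: names as homozygous one-locus genotypes."""
    return pairwise_fst(name_dataset(ds), grouping, n_perm=n_perm, seed=seed,
                        mode="variety_name")


# ---------------------------------------------------------------------------
# hierarchical AMOVA
# ---------------------------------------------------------------------------

def shared_alleles_matrix(ds: GenotypeDataset, locus: int) -> tuple[np.ndarray, np.ndarray]:
    """(shared, both_typed) for one locus: multiset intersection size (0/1/2)
    between the unordered genotype pairs of every two individuals."""
    a1, a2 = ds.calls[:, locus, 0], ds.calls[:, locus, 1]
    valid = a1 != MISSING
    e11 = a1[:, None] == a1[None, :]
    e12 = a1[:, None] == a2[None, :]
    e21 = a2[:, None] == a1[None, :]
    e22 = a2[:, None] == a2[None, :]
    same_multiset = (e11 & e22) | (e12 & e21)
    any_common = e11 | e12 | e21 | e22
    shared = np.where(same_multiset, 2, any_common.astype(int))
    return shared, valid[:, None] & valid[None, :]


def allele_difference_matrix(ds: GenotypeDataset) -> np.ndarray:
    """Squared inter-individual distance: allele differences per locus
    (0/1/2, unordered-pair multiset mismatch) summed over mutually typed loci."""
    n = ds.n_individuals
    d = np.zeros((n, n))
    for j in range(ds.n_loci):
        shared, both = shared_alleles_matrix(ds, j)
        d += np.where(both, 2 - shared, 0)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class AmovaResult:
    components: dict            # raw sigma2_a, sigma2_b, sigma2_c
    components_truncated: dict  # negatives clipped at 0
    truncated: bool
    percentages: dict           # from raw components, sum to 100
    f_ct: float | None
    f_sc: float | None
    f_st: float | None
    p_values: dict = field(default_factory=dict)
    n_perm: int = 0
    df: dict = field(default_factory=dict)
    single_region: bool = False


def _amova_ss(d2: np.ndarray, regions: np.ndarray, zones: np.ndarray) -> tuple:
    """Sums of squares and size coefficients for zones nested in regions."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    zone_ids, zone_idx = np.unique(zones, return_inverse=True)
    region_ids, region_idx = np.unique(regions, return_inverse=True)
    ss_wz = 0.0
    zone_sizes = np.bincount(zone_idx).astype(float)
    for z in range(len(zone_ids)):
        sel = zone_idx == z
        ss_wz += d2[np.ix_(sel, sel)].sum() / (2.0 * zone_sizes[z])
    ss_wr = 0.0
    region_sizes = np.bincount(region_idx).astype(float)
    for r in range(len(region_ids)):
        sel = region_idx == r
        ss_wr += d2[np.ix_(sel, sel)].sum() / (2.0 * region_sizes[r])
    # zone -> region table for coefficients
    zone_region = np.empty(len(zone_ids), dtype=int)
    for z in range(len(zone_ids)):
        zone_region[z] = region_idx[zone_idx == z][0]
    return ss_total, ss_wr, ss_wz, zone_sizes, region_sizes, zone_region


def _amova_components(d2: np.ndarray, regions: np.ndarray, zones: np.ndarray) -> dict:
    """Raw variance components and fixation indices (no permutations)."""
    n = d2.shape[0]
    ss_total, ss_wr, ss_wz, zone_sizes, region_sizes, zone_region = _amova_ss(
        d2, regions, zones
    )
    R, Z = len(region_sizes), len(zone_sizes)
    df_a, df_b, df_c = R - 1, Z - R, n - Z
    ss_a = ss_total - ss_wr
    ss_b = ss_wr - ss_wz
    out = {"df": {"among_regions": df_a, "among_zones": df_b, "within_zones": df_c}}
    sigma_c = ss_wz / df_c if df_c > 0 else 0.0
    if df_b > 0:
        sum_nz2_over_nr = sum(
            (zone_sizes[zone_region == r] ** 2).sum() / region_sizes[r]
            for r in range(R)
        )
        n_b = (n - sum_nz2_over_nr) / df_b
        sigma_b = (ss_b / df_b - sigma_c) / n_b
    else:
        sigma_b = 0.0
    if df_a > 0:
        sum_nz2_over_nr = sum(
            (zone_sizes[zone_region == r] ** 2).sum() / region_sizes[r]
            for r in range(R)
        )
        n_ab = (sum_nz2_over_nr - (zone_sizes**2).sum() / n) / df_a
        n_a = (n - (region_sizes**2).sum() / n) / df_a
        sigma_a = (ss_a / df_a - sigma_c - n_ab * sigma_b) / n_a
    else:
        sigma_a = 0.0
    out["sigma"] = {"a": sigma_a, "b": sigma_b, "c": sigma_c}
    total = sigma_a + sigma_b + sigma_c
    if total > 0:
        out["f_ct"] = sigma_a / total if df_a > 0 else None
        out["f_sc"] = sigma_b / (sigma_b + sigma_c) if df_b > 0 and (sigma_b + sigma_c) > 0 else None
        out["f_st"] = (sigma_a + sigma_b) / total
    else:
        out["f_ct"] = out["f_sc"] = out["f_st"] = None
    return out


def amova(ds: GenotypeDataset, n_perm: int = 10000, seed: int | None = None) -> AmovaResult:
    """Hierarchical AMOVA of zones nested within regions.

    Components come from mean squares with unequal-size coefficients;
    negative components are reported raw (indices use raw values) and also
    truncated at 0 with a flag.  Permutation schemes: F_SC permutes
    individuals among zones within regions; F_CT permutes whole zones among
    regions; F_ST permutes individuals among zones regardless of region.
    p = (#{perm >= obs} + 1) / (n_perm + 1).
    """
    m = ds.meta
    regions = m["region"].to_numpy()
    zones = m["zone"].to_numpy()
    region_of_zone = {z: m.loc[m["zone"] == z, "region"].iloc[0] for z in set(zones)}
    if any(m.groupby("zone").size() < 2):
        raise ValueError("every zone needs >= 2 individuals")
    d2 = allele_difference_matrix(ds)
    obs = _amova_components(d2, regions, zones)
    sigma = obs["sigma"]
    single_region = len(set(regions)) < 2
    total = sum(sigma.values())
    percentages = (
        {k: 100.0 * v / total for k, v in sigma.items()} if total > 0 else
        {k: np.nan for k in sigma}
    )
    truncated = any(v < 0 for v in sigma.values())
    result = AmovaResult(
        components=dict(sigma),
        components_truncated={k: max(0.0, v) for k, v in sigma.items()},
        truncated=truncated,
        percentages=percentages,
        f_ct=obs["f_ct"], f_sc=obs["f_sc"], f_st=obs["f_st"],
        n_perm=n_perm, df=obs["df"], single_region=single_region,
    )
    if n_perm <= 0 or total <= 0:
        return result

    rng = np.random.default_rng(seed)
    zone_list = sorted(set(zones))
    zperm_regions = np.array([region_of_zone[z] for z in zone_list], dtype=object)
    counts = {"f_sc": 0, "f_ct": 0, "f_st": 0}
    valid_perms = {"f_sc": 0, "f_ct": 0, "f_st": 0}

    # F_SC: individuals among zones within regions
    if obs["f_sc"] is not None:
        zl = zones.copy()
        for _ in range(n_perm):
            for r in set(regions):
                sel = np.flatnonzero(regions == r)
                zl[sel] = zl[sel[rng.permutation(len(sel))]]
            stat = _amova_components(d2, regions, zl)["f_sc"]
            if stat is not None:
                valid_perms["f_sc"] += 1
                if stat >= obs["f_sc"] - 1e-15:
                    counts["f_sc"] += 1

    # F_CT: whole zones among regions (keep zone count per region)
    if obs["f_ct"] is not None and len(zone_list) > len(set(regions)):
        for _ in range(n_perm):
            shuffled = zperm_regions[rng.permutation(len(zone_list))]
            z2r = dict(zip(zone_list, shuffled))
            rl = np.array([z2r[z] for z in zones], dtype=object)
            stat = _amova_components(d2, rl, zones)["f_ct"]
            if stat is not None:
                valid_perms["f_ct"] += 1
                if stat >= obs["f_ct"] - 1e-15:
                    counts["f_ct"] += 1

    # F_ST: individuals among zones without respect to region
    if obs["f_st"] is not None:
        order = np.arange(len(zones))
        for _ in range(n_perm):
            perm = rng.permutation(order)
            zl = zones[perm]
            rl = np.array([region_of_zone[z] for z in zl], dtype=object)
            stat = _amova_components(d2, rl, zl)["f_st"]
            if stat is not None:
                valid_perms["f_st"] += 1
                if stat >= obs["f_st"] - 1e-15:
                    counts["f_st"] += 1

    result.p_values = {
        k: (counts[k] + 1) / (valid_perms[k] + 1) if valid_perms[k] else None
        for k in counts
    }
    return result
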