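"""Within-group diversity statistics and between-group comparisons.

Per group and locus: allele count N_a, Nei's unbiased expected
heterozygosity H_e = n/(n-1) * (1 - sum p_i^2) over n non-missing gene
copies, and allelic richness R_s rarefied to a common gene-copy count g via
the hypergeometric formula R_s = sum_i [1 - C(n - n_i, g) / C(n, g)].
Groups are compared per statistic with exact Wilcoxon signed-rank tests
pairing the per-locus values, and summarised with significance letters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from divkit.data_model import MISSING, GenotypeDataset, GroupingKey


def allele_counts(ds: GenotypeDataset, grouping: GroupingKey) -> dict[str, dict[str, dict[int, int]]]:
    """group -> locus -> {allele: gene-copy count} over non-missing calls."""
    labels = grouping.labels_for(ds.individuals)
    out: dict[str, dict[str, dict[int, int]]] = {}
    for g in sorted(set(labels)):
        sub = ds.calls[labels == g]
        per_locus = {}
        for j, locus in enumerate(ds.loci):
            vals = sub[:, j, :].ravel()
            vals = vals[vals != MISSING]
            uniq, cnt = np.unique(vals, return_counts=True)
            per_locus[locus] = dict(zip(uniq.tolist(), cnt.tolist()))
        out[g] = per_locus
    return out


def expected_heterozygosity(counts: dict[int, int] | list[int]) -> float | None:
    """Nei's unbiased H_e; None when fewer than 2 gene copies are typed."""
    c = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts, dtype=float)
    n = c.sum()
    if n < 2:
        return None
    p = c / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


def allelic_richness(counts: dict[int, int] | list[int], g: int) -> float:
    """Expected allele count in a subsample of g gene copies (rarefaction)."""
    c = [v for v in (counts.values() if isinstance(counts, dict) else counts) if v > 0]
    n = sum(c)
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2 gene copies")
    if g > n:
        raise ValueError(
            f"g={g} exceeds the {n} typed gene copies; drop the group or lower g"
        )
    denom = comb(n, g)
    return float(sum(1.0 - comb(n - ni, g) / denom for ni in c))


def count_heterozygotes(ds: GenotypeDataset, grouping: GroupingKey) -> dict[str, int]:
    """Individuals heterozygous at >= 1 locus, per group (counted once each)."""
    labels = grouping.labels_for(ds.individuals)
    het = (
        (ds.calls[:, :, 0] != ds.calls[:, :, 1])
        & (ds.calls[:, :, 0] != MISSING)
    ).any(axis=1)
    return {g: int(het[labels == g].sum()) for g in sorted(set(labels))}


def private_alleles(ds: GenotypeDataset, grouping: GroupingKey) -> pd.DataFrame:
    """Alleles present in exactly one group, with their within-group frequency."""
    counts = allele_counts(ds, grouping)
    if len(counts) < 2:
        raise ValueError("private alleles need >= 2 groups")
    rows = []
    for locus in ds.loci:
        owners: dict[int, list[str]] = {}
        for g, per_locus in counts.items():
            for a in per_locus[locus]:
                owners.setdefault(a, []).append(g)
        for a, gs in owners.items():
            if len(gs) == 1:
                g = gs[0]
                total = sum(counts[g][locus].values())
                rows.append({
                    "locus": locus, "allele": a, "group": g,
                    "frequency": counts[g][locus][a] / total,
                })
    return pd.DataFrame(rows, columns=["locus", "allele", "group", "frequency"])


def _genotype_key(calls_row: np.ndarray) -> tuple:
    # missing is incomparable, not a wildcard: the missingness pattern is part
    # of the identity, so individuals differing only by missingness never merge
    return tuple((int(a), int(b)) for a, b in calls_row)


def multilocus_genotypes(ds: GenotypeDataset, grouping: GroupingKey | None = None) -> dict:
    """Distinct multilocus genotypes; those shared between groups listed.

    Returns ``{"n_genotypes": int, "shared": DataFrame}`` where ``shared``
    has one row per genotype found in > 1 group, with the groups and the
    variety-name sets carried in each.
    """
    keys = [_genotype_key(ds.calls[i]) for i in range(ds.n_individuals)]
    n_genotypes = len(set(keys))
    shared_rows = []
    if grouping is not None:
        labels = grouping.labels_for(ds.individuals)
        varieties = ds.meta["variety"].to_numpy()
        by_key: dict[tuple, list[int]] = {}
        for i, k in enumerate(keys):
            by_key.setdefault(k, []).append(i)
        for k, idx in by_key.items():
            gs = sorted(set(labels[idx]))
            if len(gs) > 1:
                shared_rows.append({
                    "groups": tuple(gs),
                    "n_individuals": len(idx),
                    "varieties": {
                        g: sorted(set(varieties[i] for i in idx if labels[i] == g))
                        for g in gs
                    },
                })
    return {"n_genotypes": n_genotypes,
            "shared": pd.DataFrame(shared_rows, columns=["groups", "n_individuals", "varieties"])}


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank and significance letters
# ---------------------------------------------------------------------------

def exact_signed_rank_p(x: np.ndarray, y: np.ndarray) -> float | None:
    """Two-sided exact signed-rank p pairing per-locus values of two groups.

    Zero differences are dropped (Wilcoxon's original treatment); ties in
    |d| get average ranks; the null distribution is enumerated over all 2^n
    sign patterns (n <= 20).  Returns None with < 4 non-zero differences,
    where the exact test cannot reach conventional levels.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0  # identical paired values: no evidence of any difference
    if n < 4:
        return None
    if n > 20:
        raise ValueError("exact enumeration limited to 20 non-zero differences")
    ranks = pd.Series(np.abs(d)).rank(method="average").to_numpy()
    w_obs = ranks[d > 0].sum()
    signs = np.array(list(itertools.product([0, 1], repeat=n)), dtype=float)
    w_all = signs @ ranks
    m = ranks.sum()
    lo, hi = min(w_obs, m - w_obs), max(w_obs, m - w_obs)
    p = (np.sum(w_all <= lo + 1e-9) + np.sum(w_all >= hi - 1e-9)) / len(w_all)
    return float(min(1.0, p))


def significance_letters(groups: list[str], pvals: dict[tuple[str, str], float | None],
                         alpha: float = 0.01) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not significantly
    different.  Greedy insert over the deterministic input order."""

    def differs(a: str, b: str) -> bool:
        p = pvals.get((a, b), pvals.get((b, a)))
        return p is not None and p < alpha

    cliques: list[list[str]] = []
    for g in groups:
        placed = False
        for clique in cliques:
            if all(not differs(g, m) for m in clique):
                clique.append(g)
                placed = True
        if not placed:
            cliques.append([g])
    # expansion pass: groups created before a later clique may belong in it
    for clique in cliques:
        for g in groups:
            if g not in clique and all(not differs(g, m) for m in clique):
                clique.append(g)
    for clique in cliques:
        clique.sort(key=groups.index)
    # absorb redundant cliques (subset of another)
    keep = []
    for i, c in enumerate(cliques):
        if any(set(c) < set(o) for o in cliques) or any(set(c) == set(o) for o in keep):
            continue
        keep.append(c)
    letters = {g: "" for g in groups}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", keep):
        for g in clique:
            letters[g] += letter
    return letters


def compare_groups(per_locus_values: dict[str, np.ndarray], alpha: float = 0.01) -> pd.DataFrame:
    """Pairwise exact signed-rank tests on paired per-locus values + letters.

    ``per_locus_values`` maps group -> array of one statistic (H_e or R_s)
    per locus, aligned across groups.  Returns a table with pairwise
    p-values and a letters column at the chosen threshold.
    """
    groups = list(per_locus_values)
    pvals: dict[tuple[str, str], float | None] = {}
    for a, b in itertools.combinations(groups, 2):
        pvals[(a, b)] = (
            1.0 if a == b else exact_signed_rank_p(per_locus_values[a], per_locus_values[b])
        )
    letters = significance_letters(groups, pvals, alpha=alpha)
    rows = [
        {"group_1": a, "group_2": b, "p_value": p,
         "significant": (p is not None and p < alpha)}
        for (a, b), p in pvals.items()
    ]
    df = pd.DataFrame(rows, columns=["group_1", "group_2", "p_value", "significant"])
    df.attrs["letters"] = letters
    return df


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

@dataclass
class DiversityTable:
    """Per-group means of N_a / H_e / R_s plus NbHet, with per-locus detail."""

    per_locus: pd.DataFrame   # (group, locus) rows
    per_group: pd.DataFrame   # group rows with means, NbHet, n
    rarefaction_g: int
    he_estimator: str = "nei_unbiased"

    def per_locus_values(self, statistic: str) -> dict[str, np.ndarray]:
        piv = self.per_locus.pivot(index="locus", columns="group", values=statistic)
        return {g: piv[g].to_numpy() for g in piv.columns}


def diversity_table(ds: GenotypeDataset, grouping: GroupingKey,
                    rarefy_min_individuals: int) -> DiversityTable:
    """Build the standard group x locus diversity table.

    ``rarefy_min_individuals`` is the smallest per-group sample size (diploid
    individuals); rarefaction uses g = 2 * that many gene copies.  Loci where
    a group has fewer typed copies than g get R_s = NaN for that group.
    """
    g_copies = 2 * rarefy_min_individuals
    counts = allele_counts(ds, grouping)
    labels = grouping.labels_for(ds.individuals)
    nbhet = count_heterozygotes(ds, grouping)
    rows = []
    for grp, per_locus in counts.items():
        for locus, c in per_locus.items():
            n = sum(c.values())
            rows.append({
                "group": grp, "locus": locus, "n_copies": n,
                "n_a": len(c),
                "h_e": expected_heterozygosity(c),
                "r_s": allelic_richness(c, g_copies) if n >= g_copies else np.nan,
            })
    per_locus_df = pd.DataFrame(rows)
    per_group = (
        per_locus_df.groupby("group")[["n_a", "h_e", "r_s"]].mean().rename(
            columns={"n_a": "N_a", "h_e": "H_e", "r_s": "R_s"}
        )
    )
    per_group["NbHet"] = pd.Series(nbhet)
    per_group["n"] = pd.Series(
        {g: int((labels == g).sum()) for g in per_group.index}
    )
    return DiversityTable(per_locus_df, per_group, rarefaction_g=g_copies)
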