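"""Independent brute-force oracles, written before the optimised paths.

These stay deliberately naive: plain Python loops, exhaustive enumeration,
and scalar arithmetic, so they cannot share a bug with the vectorised
implementations they check.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np


def rarefaction_enumeration(counts: list[int], g: int) -> float:
    """Mean number of distinct alleles over ALL subsets of g gene copies."""
    copies = []
    for allele, c in enumerate(counts):
        copies.extend([allele] * c)
    labelled = [len(set(copies[i] for i in sub))
                for sub in itertools.combinations(range(len(copies)), g)]
    return float(np.mean(labelled))


def he_draw_two_oracle(counts: list[int]) -> float:
    """Probability two gene copies drawn without replacement differ."""
    n = sum(counts)
    same = sum(c * (c - 1) for c in counts)
    return 1.0 - same / (n * (n - 1))


def wc_theta_oracle(genotypes: list[list[tuple]], groups: list[int]) -> float | None:
    """Weir-Cockerham theta by direct scalar transcription.

    ``genotypes[i][l]`` is an (a1, a2) tuple or None for missing; ``groups``
    assigns each individual to a group index.
    """
    n_loci = len(genotypes[0])
    sum_a = sum_abc = 0.0
    any_locus = False
    for l in range(n_loci):
        rows = [(g, geno[l]) for g, geno in zip(groups, genotypes) if geno[l] is not None]
        group_ids = sorted({g for g, _ in rows})
        sizes = {g: sum(1 for gg, _ in rows if gg == g) for g in group_ids}
        group_ids = [g for g in group_ids if sizes[g] >= 2]
        if len(group_ids) < 2:
            continue
        rows = [(g, pair) for g, pair in rows if g in group_ids]
        alleles = sorted({a for _, pair in rows for a in pair})
        if len(alleles) < 2:
            continue
        r = len(group_ids)
        n_i = [sizes[g] for g in group_ids]
        n_tot = sum(n_i)
        nbar = n_tot / r
        nc = (n_tot - sum(x * x for x in n_i) / n_tot) / (r - 1)
        for allele in alleles:
            p_i, h_i = [], []
            for g in group_ids:
                pairs = [pair for gg, pair in rows if gg == g]
                copies = sum(pair.count(allele) for pair in pairs)
                het = sum(1 for pair in pairs
                          if allele in pair and pair[0] != pair[1])
                p_i.append(copies / (2 * len(pairs)))
                h_i.append(het / len(pairs))
            pbar = sum(n * p for n, p in zip(n_i, p_i)) / n_tot
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(n_i, h_i)) / n_tot
            a = nbar / nc * (
                s2 - 1.0 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
            )
            b = nbar / (nbar - 1) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            sum_a += a
            sum_abc += a + b + c
        any_locus = True
    if not any_locus or sum_abc == 0.0:
        return None
    return sum_a / sum_abc


def pair_distance_oracle(g1: list, g2: list) -> float:
    """Allele-difference count between two multilocus genotypes (None = missing)."""
    d = 0
    for p1, p2 in zip(g1, g2):
        if p1 is None or p2 is None:
            continue
        c1, c2 = Counter(p1), Counter(p2)
        shared = sum((c1 & c2).values())
        d += 2 - shared
    return float(d)


def amova_oracle(d2: np.ndarray, regions: list, zones: list) -> dict:
    """Hierarchical AMOVA components by explicit pair loops.

    Returns sigma components, percentages and indices computed from the
    textbook mean-square equations with unequal-size coefficients.
    """
    n = len(regions)
    region_ids = sorted(set(regions))
    zone_ids = sorted(set(zones))

    def ss_within(partition: dict) -> float:
        total = 0.0
        for members in partition.values():
            m = len(members)
            s = 0.0
            for i in members:
                for j in members:
                    s += d2[i, j]
            total += s / (2 * m)
        return total

    everyone = {None: list(range(n))}
    by_zone = {z: [i for i in range(n) if zones[i] == z] for z in zone_ids}
    by_region = {r: [i for i in range(n) if regions[i] == r] for r in region_ids}
    ss_total = ss_within(everyone)
    ss_wz = ss_within(by_zone)
    ss_wr = ss_within(by_region)
    R, Z = len(region_ids), len(zone_ids)
    df_a, df_b, df_c = R - 1, Z - R, n - Z
    sigma_c = ss_wz / df_c if df_c else 0.0
    n_z = {z: len(m) for z, m in by_zone.items()}
    n_r = {r: len(m) for r, m in by_region.items()}
    zone_region = {z: regions[by_zone[z][0]] for z in zone_ids}
    sum_nz2_over_nr = sum(
        sum(n_z[z] ** 2 for z in zone_ids if zone_region[z] == r) / n_r[r]
        for r in region_ids
    )
    if df_b:
        nb = (n - sum_nz2_over_nr) / df_b
        sigma_b = ((ss_wr - ss_wz) / df_b - sigma_c) / nb
    else:
        sigma_b = 0.0
    if df_a:
        n_ab = (sum_nz2_over_nr - sum(v**2 for v in n_z.values()) / n) / df_a
        n_a = (n - sum(v**2 for v in n_r.values()) / n) / df_a
        sigma_a = ((ss_total - ss_wr) / df_a - sigma_c - n_ab * sigma_b) / n_a
    else:
        sigma_a = 0.0
    total = sigma_a + sigma_b + sigma_c
    return {
        "sigma": {"a": sigma_a, "b": sigma_b, "c": sigma_c},
        "f_ct": sigma_a / total if total else None,
        "f_sc": sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) else None,
        "f_st": (sigma_a + sigma_b) / total if total else None,
    }


def additive_tree_random(rng: np.random.Generator, n_leaves: int):
    """Random unrooted binary tree with positive lengths + its distance matrix.

    Built by sequential leaf attachment; distances accumulated by explicit
    path tracking in an adjacency map.
    """
    # nodes: 0..n_leaves-1 leaves; internal nodes appended
    adj: dict[int, dict[int, float]] = {}

    def connect(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def disconnect(a, b):
        del adj[a][b]
        del adj[b][a]

    next_node = n_leaves
    connect(0, 1, float(rng.uniform(0.1, 1.0)))
    edges = [(0, 1)]
    for leaf in range(2, n_leaves):
        a, b = edges[rng.integers(len(edges))]
        w = adj[a][b]
        mid = next_node
        next_node += 1
        disconnect(a, b)
        split = float(rng.uniform(0.2, 0.8)) * w
        connect(a, mid, split)
        connect(mid, b, w - split)
        connect(mid, leaf, float(rng.uniform(0.1, 1.0)))
        edges.remove((a, b))
        edges.extend([(a, mid), (mid, b), (mid, leaf)])
    # all-pairs leaf distances by BFS
    import collections

    dm = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        dq = collections.deque([src])
        while dq:
            u = dq.popleft()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    dq.append(v)
        for dst in range(n_leaves):
            dm[src, dst] = dist[dst]
    return dm
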