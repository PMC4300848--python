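"""Simple-matching dissimilarity, neighbor-joining, and locus bootstrap.

The simple-matching dissimilarity between two diploid individuals is
1 minus the mean per-locus proportion of shared alleles (0, 1/2 or 1 per
locus, over mutually typed loci).  Trees are unrooted NJ dendrograms:
``classic`` is the Saitou-Nei agglomeration (consistent on additive
distances); ``weighted`` replaces the even 1/2 average in the distance
reduction with a subtree-size-weighted average,
``d(u,k) = (w_i (d(i,k) - b_i) + w_j (d(j,k) - b_j)) / (w_i + w_j)``
where ``b`` are the branch lengths to the new node ``u``.  Edge support is
the percentage of locus-bootstrap replicate trees containing the same leaf
bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from divkit.data_model import GenotypeDataset
from divkit.differentiation import shared_alleles_matrix


@dataclass
class DistanceMatrix:
    labels: list
    matrix: np.ndarray
    loci_used: np.ndarray | None = None  # per-pair count of mutually typed loci

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape inconsistent with labels")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix diagonal must be 0")
        self.matrix = m


def per_locus_match_scores(ds: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """(L, n, n) match score in {0, 1/2, 1} per locus and typed mask."""
    n = ds.n_individuals
    scores = np.zeros((ds.n_loci, n, n))
    typed = np.zeros((ds.n_loci, n, n), dtype=bool)
    for j in range(ds.n_loci):
        shared, both = shared_alleles_matrix(ds, j)
        scores[j] = shared / 2.0
        typed[j] = both
    return scores, typed


def simple_matching(ds: GenotypeDataset, locus_index: np.ndarray | None = None) -> DistanceMatrix:
    """d(i,j) = 1 - mean per-locus shared-allele proportion.

    ``locus_index`` resamples loci (bootstrap); a pair with no mutually
    typed locus is an error naming the pair.
    """
    if ds.n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    scores, typed = per_locus_match_scores(ds)
    if locus_index is not None:
        scores, typed = scores[locus_index], typed[locus_index]
    n_used = typed.sum(axis=0)
    if (n_used == 0).any():
        i, j = np.argwhere(n_used == 0)[0]
        if i != j:
            raise ValueError(
                f"no mutually typed locus for pair "
                f"({ds.individuals[i]}, {ds.individuals[j]})"
            )
    with np.errstate(invalid="ignore"):
        mean_match = np.where(n_used > 0, (scores * typed).sum(axis=0) / n_used, 1.0)
    d = 1.0 - mean_match
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(ds.individuals), d, loci_used=n_used)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class Node:
    label: str | None = None
    children: list = field(default_factory=list)  # (child Node, branch length)
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.label]
        out = []
        for ch, _ in self.children:
            out.extend(ch.leaves())
        return out


@dataclass
class NJTree:
    root: Node                  # internal anchor of the unrooted tree
    labels: list
    negative_branches_truncated: int = 0

    def newick(self) -> str:
        def fmt(node: Node, length: float | None) -> str:
            if node.is_leaf():
                core = node.label
            else:
                inner = ",".join(fmt(ch, bl) for ch, bl in node.children)
                sup = "" if node.support is None else f"{node.support:g}"
                core = f"({inner}){sup}"
            return core if length is None else f"{core}:{length:.6g}"

        return fmt(self.root, None) + ";"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions (as the smaller-or-canonical side)."""
        all_leaves = frozenset(self.labels)
        parts: set[frozenset] = set()

        def walk(node: Node) -> frozenset:
            if node.is_leaf():
                return frozenset([node.label])
            acc: set = set()
            for ch, _ in node.children:
                below = walk(ch)
                if 1 < len(below) < len(all_leaves) - 1:
                    other = all_leaves - below
                    parts.add(min(below, other, key=lambda s: (len(s), sorted(s))))
                acc |= below
            return frozenset(acc)

        walk(self.root)
        return parts

    def internal_edges(self) -> list[frozenset]:
        return sorted(self.bipartitions(), key=lambda s: (len(s), sorted(s)))

    def patristic(self) -> pd.DataFrame:
        """Leaf-to-leaf path-length matrix."""
        dists: dict[str, dict[str, float]] = {}

        def down(node: Node, acc: float, origin: str) -> None:
            if node.is_leaf():
                dists[origin][node.label] = acc
                return
            for ch, bl in node.children:
                down(ch, acc + bl, origin)

        def collect(node: Node, path: list) -> None:
            if node.is_leaf():
                dists[node.label] = {}
                acc = 0.0
                for parent, bl, siblings in reversed(path):
                    acc += bl
                    for sib, sbl in siblings:
                        down(sib, acc + sbl, node.label)
                return
            for ch, bl in node.children:
                sibs = [(c, l) for c, l in node.children if c is not ch]
                collect(ch, path + [(node, bl, sibs)])

        collect(self.root, [])
        df = pd.DataFrame(0.0, index=self.labels, columns=self.labels)
        for a in self.labels:
            for b, v in dists[a].items():
                df.loc[a, b] = v
        return df


def nj_build(dm: DistanceMatrix, variant: str = "classic") -> NJTree:
    """Neighbor-joining agglomeration on a complete distance matrix (n >= 3).

    Negative branch lengths are truncated to 0 and counted on the result.
    """
    if variant not in ("classic", "weighted"):
        raise ValueError(f"unknown NJ variant {variant!r}")
    d = dm.matrix.astype(float).copy()
    if np.isnan(d).any():
        raise ValueError("incomplete distance matrix")
    n = len(dm.labels)
    if n < 3:
        raise ValueError("NJ needs >= 3 leaves")
    nodes = [Node(label=l) for l in dm.labels]
    sizes = [1] * n
    active = list(range(n))
    truncated = 0

    def clip(x: float) -> float:
        nonlocal truncated
        if x < 0:
            truncated += 1
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        ai, aj = active[i_], active[j_]
        dij = d[ai, aj]
        bi = 0.5 * dij + (r[i_] - r[j_]) / (2.0 * (m - 2))
        bj = dij - bi
        bi, bj = clip(bi), clip(bj)
        new = Node(children=[(nodes[ai], bi), (nodes[aj], bj)])
        wi, wj = sizes[ai], sizes[aj]
        knew = np.empty(d.shape[0] + 1)
        for k in active:
            if k in (ai, aj):
                continue
            if variant == "classic":
                dk = 0.5 * (d[ai, k] + d[aj, k] - dij)
            else:
                dk = (wi * (d[ai, k] - bi) + wj * (d[aj, k] - bj)) / (wi + wj)
            knew[k] = dk
        d = np.pad(d, ((0, 1), (0, 1)))
        idx_new = d.shape[0] - 1
        for k in active:
            if k not in (ai, aj):
                d[idx_new, k] = d[k, idx_new] = knew[k]
        nodes.append(new)
        sizes.append(wi + wj)
        active = [k for k in active if k not in (ai, aj)] + [idx_new]

    # final three-point join
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = Node(children=[(nodes[a], clip(la)), (nodes[b], clip(lb)), (nodes[c], clip(lc))])
    return NJTree(root, list(dm.labels), negative_branches_truncated=truncated)


def bootstrap_support(ds: GenotypeDataset, n_boot: int = 1000, seed: int | None = None,
                      variant: str = "classic", min_support: float | None = None) -> tuple[NJTree, pd.DataFrame]:
    """Locus bootstrap: resample loci with replacement, rebuild NJ trees, and
    map bipartition percentages onto the reference tree.

    Returns the annotated reference tree and a table of internal-edge
    supports (``min_support`` only filters the table, not the annotation).
    """
    ref = nj_build(simple_matching(ds), variant=variant)
    if n_boot <= 0:
        return ref, pd.DataFrame(columns=["bipartition", "support"])
    rng = np.random.default_rng(seed)
    ref_parts = ref.bipartitions()
    hits = {p: 0 for p in ref_parts}
    for _ in range(n_boot):
        idx = rng.integers(0, ds.n_loci, size=ds.n_loci)
        t = nj_build(simple_matching(ds, locus_index=idx), variant=variant)
        for p in t.bipartitions():
            if p in hits:
                hits[p] += 1
    support = {p: 100.0 * h / n_boot for p, h in hits.items()}

    def annotate(node: Node) -> frozenset:
        if node.is_leaf():
            return frozenset([node.label])
        below: set = set()
        for ch, _ in node.children:
            below |= annotate(ch)
        fs = frozenset(below)
        other = frozenset(ref.labels) - fs
        key = min(fs, other, key=lambda s: (len(s), sorted(s)))
        if key in support and 1 < len(fs) < len(ref.labels) - 1:
            node.support = support[key]
        return fs

    annotate(ref.root)
    rows = [
        {"bipartition": tuple(sorted(p)), "support": s}
        for p, s in sorted(support.items(), key=lambda kv: -kv[1])
        if min_support is None or s > min_support
    ]
    return ref, pd.DataFrame(rows, columns=["bipartition", "support"])


def cluster_composition(clusters: dict[str, list[str]], classes: pd.DataFrame) -> pd.DataFrame:
    """Spike-class and stature-class frequencies per cluster of populations.

    ``classes`` is the per-population table from
    :func:`divkit.morphology.classify_populations`.
    """
    rows = []
    for name, members in clusters.items():
        if len(members) == 0:
            raise ValueError(f"cluster {name!r} is empty")
        missing = [m for m in members if m not in classes.index]
        if missing:
            raise ValueError(f"cluster {name!r} members without classes: {missing[:5]}")
        sub = classes.loc[members]
        row = {"cluster": name, "n": len(members)}
        for col, prefix in (("spike_class", "spike"), ("stature_class", "stature")):
            freq = sub[col].value_counts(normalize=True)
            for cls, f in freq.items():
                row[f"{prefix}:{cls}"] = f
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster").fillna(0.0)
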