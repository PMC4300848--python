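"""Discriminant analysis of principal components (DAPC), from scratch.

Individuals are encoded as allele-count vectors (0/1/2 per allele column,
column-mean imputation for missing calls), centered, and reduced by PCA.
K-means over a grid of K with a BIC score, ``BIC(K) = n ln(W_K / n) +
K ln(n)`` (W_K = total within-cluster sum of squares on the retained PC
scores), selects the number of clusters; linear discriminant functions are
then fit on a reduced number of PCs chosen by the a-score (observed
reassignment success minus its expectation under random group labels).
Membership probabilities use a Gaussian kernel on the distance to cluster
centroids in discriminant space.  Supplementary individuals are projected
through the *training* centering, PCA and discriminant loadings without any
refitting.  Cluster labels are arbitrary: all comparisons across runs go
through label-free metagroup mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.cluster import KMeans

from divkit.data_model import MISSING, GenotypeDataset


# ---------------------------------------------------------------------------
# encoding and PCA
# ---------------------------------------------------------------------------

@dataclass
class PCABasis:
    columns: list            # (locus, allele) per design-matrix column
    col_means: np.ndarray    # training means (also the imputation values)
    components: np.ndarray   # (p, rank) orthonormal
    eigenvalues: np.ndarray
    scale: np.ndarray | None = None
    dropped_loci: list = field(default_factory=list)

    @property
    def loci(self) -> set:
        return {loc for loc, _ in self.columns}


def _allele_count_matrix(ds: GenotypeDataset, columns: list | None = None
                         ) -> tuple[np.ndarray, list, np.ndarray, list]:
    """(raw counts with NaN for missing, columns, missing mask, dropped loci)."""
    dropped = []
    if columns is None:
        columns = []
        for j, locus in enumerate(ds.loci):
            alleles = sorted(set(ds.calls[:, j, :].ravel()) - {MISSING})
            if not alleles:
                dropped.append(locus)
                continue
            columns.extend((locus, a) for a in alleles)
    col_of = {}
    for k, (locus, a) in enumerate(columns):
        col_of.setdefault(locus, {})[a] = k
    X = np.zeros((ds.n_individuals, len(columns)))
    miss = np.zeros_like(X, dtype=bool)
    for j, locus in enumerate(ds.loci):
        if locus not in col_of:
            continue
        cols = col_of[locus]
        a1, a2 = ds.calls[:, j, 0], ds.calls[:, j, 1]
        for i in range(ds.n_individuals):
            if a1[i] == MISSING:
                for k in cols.values():
                    miss[i, k] = True
                continue
            for a in (a1[i], a2[i]):
                k = cols.get(int(a))
                if k is not None:
                    X[i, k] += 1
    return X, columns, miss, dropped


def encode_and_reduce(ds: GenotypeDataset, scale: bool = False
                      ) -> tuple[np.ndarray, PCABasis]:
    """Centered allele-count design matrix -> (PC scores, PCA basis).

    Missing calls are imputed with the column mean (i.e. twice the allele
    frequency) before centering; all-missing loci are dropped with a
    warning; the PCA basis is orthonormal and complete (all non-null axes),
    so reconstruction from all scores is exact.
    """
    if ds.n_individuals < 3:
        raise ValueError("PCA reduction needs >= 3 individuals")
    X, columns, miss, dropped = _allele_count_matrix(ds)
    if dropped:
        warnings.warn(f"all-missing loci dropped: {dropped}")
    with np.errstate(invalid="ignore"):
        obs_means = np.where(
            (~miss).sum(axis=0) > 0,
            np.where(miss, 0, X).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1),
            0.0,
        )
    X = np.where(miss, obs_means[None, :], X)
    sd = None
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = X / sd
        obs_means_scaled = X.mean(axis=0)
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > 1e-9 * (s[0] if len(s) and s[0] > 0 else 1.0)
    components = vt[keep].T
    scores = Xc @ components
    basis = PCABasis(
        columns=columns,
        col_means=obs_means if not scale else obs_means,  # raw-unit means
        components=components,
        eigenvalues=(s[keep] ** 2) / max(ds.n_individuals - 1, 1),
        scale=sd,
        dropped_loci=dropped,
    )
    return scores, basis


# ---------------------------------------------------------------------------
# K selection by BIC over K-means
# ---------------------------------------------------------------------------

@dataclass
class KSelection:
    bic: np.ndarray          # BIC(K) for K = 1..k_max
    wss: np.ndarray          # best within-cluster SS per K
    suggested_k: int         # elbow rule
    argmin_k: int
    labels: dict             # K -> best-run labels


def _best_kmeans(x: np.ndarray, k: int, n_repeats: int, rng: np.random.Generator,
                 prev_centers: np.ndarray | None, retry_cap: int = 5):
    best = None
    for attempt in range(retry_cap):
        seeds = rng.integers(0, 2**31 - 1, size=n_repeats + 1)
        fits = []
        km = KMeans(n_clusters=k, n_init=max(n_repeats, 1), random_state=int(seeds[0]))
        fits.append(km.fit(x))
        if prev_centers is not None and len(prev_centers) == k - 1:
            # split init: previous centers plus the worst-fit point, which
            # guarantees W_K <= W_{K-1} for the best-of runs
            d2 = ((x[:, None, :] - prev_centers[None]) ** 2).sum(axis=2).min(axis=1)
            init = np.vstack([prev_centers, x[np.argmax(d2)]])
            km2 = KMeans(n_clusters=k, init=init, n_init=1)
            fits.append(km2.fit(x))
        fits = [f for f in fits if len(np.unique(f.labels_)) == k]
        if fits:
            best = min(fits, key=lambda f: f.inertia_)
            return best
    raise RuntimeError(f"K-means produced an empty cluster for K={k} in every retry")


def select_k(scores: np.ndarray, k_max: int = 40, n_repeats: int = 4,
             seed: int | None = None, n_pc: int | None = None,
             rel_threshold: float = 0.05) -> KSelection:
    """BIC(K) curve over successive K-means and an elbow suggestion.

    The suggestion is the smallest K whose improvement to K+1 drops below
    ``rel_threshold`` times the largest improvement on the curve; the full
    curve is returned for the analyst's own (visual) choice.
    """
    n = scores.shape[0]
    if k_max >= n:
        raise ValueError("k_max must be < number of individuals")
    x = scores[:, :n_pc] if n_pc is not None else scores
    rng = np.random.default_rng(seed)
    wss = np.empty(k_max)
    labels: dict[int, np.ndarray] = {}
    prev_centers = None
    for k in range(1, k_max + 1):
        if k == 1:
            center = x.mean(axis=0)
            wss[0] = ((x - center) ** 2).sum()
            labels[1] = np.zeros(n, dtype=int)
            prev_centers = center[None, :]
            continue
        fit = _best_kmeans(x, k, n_repeats, rng, prev_centers)
        wss[k - 1] = min(fit.inertia_, wss[k - 2])
        labels[k] = fit.labels_
        prev_centers = fit.cluster_centers_
    with np.errstate(divide="ignore"):
        bic = n * np.log(np.maximum(wss, 1e-300) / n) + np.arange(1, k_max + 1) * np.log(n)
    drops = -np.diff(bic)  # improvement from K to K+1
    if len(drops) == 0 or drops.max() <= 0:
        suggested = 1
    else:
        thr = rel_threshold * drops.max()
        suggested = k_max
        for k in range(1, k_max + 1):
            if k == k_max or drops[k - 1] < thr:
                suggested = k
                break
    return KSelection(bic=bic, wss=wss, suggested_k=suggested,
                      argmin_k=int(np.argmin(bic)) + 1, labels=labels)


# ---------------------------------------------------------------------------
# discriminant functions
# ---------------------------------------------------------------------------

@dataclass
class DapcModel:
    basis: PCABasis
    n_pc: int
    k: int
    da_vectors: np.ndarray       # (n_pc, n_df), scaled to unit within-class var
    da_eigenvalues: np.ndarray
    centroids: np.ndarray        # (k, n_df)
    cluster_labels: np.ndarray   # training assignments
    membership: np.ndarray       # (n, k), rows sum to 1
    bic_curve: np.ndarray | None = None
    ridge_used: bool = False
    seed: int | None = None

    def coordinates(self, scores: np.ndarray) -> np.ndarray:
        return scores[:, : self.n_pc] @ self.da_vectors


def _membership_from_coords(coords: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    d2 = ((coords[:, None, :] - centroids[None]) ** 2).sum(axis=2)
    logp = -0.5 * d2
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    return p / p.sum(axis=1, keepdims=True)


def fit_discriminants(scores: np.ndarray, assignments: np.ndarray, n_pc: int,
                      basis: PCABasis | None = None) -> DapcModel:
    """Linear discriminants maximizing between/within variance on n_pc PCs.

    A singular within-class scatter is ridge-regularized (flagged).
    Membership probability of individual i in cluster k is proportional to
    exp(-d_ik^2 / 2) over discriminant coordinates.
    """
    labels = np.asarray(assignments)
    groups = np.unique(labels)
    k = len(groups)
    if k < 2:
        raise ValueError("discriminant analysis needs >= 2 clusters")
    x = scores[:, :n_pc]
    n = x.shape[0]
    overall = x.mean(axis=0)
    sw = np.zeros((n_pc, n_pc))
    sb = np.zeros((n_pc, n_pc))
    for g in groups:
        xg = x[labels == g]
        if len(xg) == 0:
            raise ValueError(f"empty cluster {g!r}")
        mg = xg.mean(axis=0)
        xc = xg - mg
        sw += xc.T @ xc
        sb += len(xg) * np.outer(mg - overall, mg - overall)
    sw /= n
    sb /= n
    ridge_used = False
    try:
        evals, evecs = scipy.linalg.eigh(sb, sw)
    except scipy.linalg.LinAlgError:
        ridge_used = True
        evals, evecs = scipy.linalg.eigh(sb, sw + 1e-8 * np.eye(n_pc))
    if not np.all(np.isfinite(evals)):
        ridge_used = True
        evals, evecs = scipy.linalg.eigh(sb, sw + 1e-8 * np.eye(n_pc))
    order = np.argsort(evals)[::-1][: k - 1]
    v = evecs[:, order]           # eigh(a, b) gives v' Sw v = I already
    ev = evals[order]
    coords = x @ v
    centroids = np.vstack([coords[labels == g].mean(axis=0) for g in groups])
    dense = np.searchsorted(groups, labels)
    membership = _membership_from_coords(coords, centroids)
    return DapcModel(
        basis=basis, n_pc=n_pc, k=k, da_vectors=v, da_eigenvalues=ev,
        centroids=centroids, cluster_labels=dense, membership=membership,
        ridge_used=ridge_used,
    )


def optimize_a_score(scores: np.ndarray, assignments: np.ndarray,
                     pc_grid: list[int] | None = None, n_sim: int = 10,
                     seed: int | None = None) -> tuple[pd.DataFrame, int]:
    """a-score curve over retained-PC counts and the argmax.

    a(n_pc) = mean over clusters of (observed correct-reassignment
    proportion - mean reassignment proportion under random labels).
    """
    labels = np.asarray(assignments)
    k = len(np.unique(labels))
    n = scores.shape[0]
    if pc_grid is None:
        hi = max(k, min(scores.shape[1], n - k - 1))
        pc_grid = sorted(set(np.linspace(max(1, k - 1), hi, num=min(10, hi), dtype=int)))
    rng = np.random.default_rng(seed)

    def reassignment(x_labels: np.ndarray, n_pc: int) -> float:
        model = fit_discriminants(scores, x_labels, n_pc)
        coords = scores[:, :n_pc] @ model.da_vectors
        assigned = np.argmin(
            ((coords[:, None, :] - model.centroids[None]) ** 2).sum(axis=2), axis=1
        )
        groups = np.unique(x_labels)
        dense = np.searchsorted(groups, x_labels)
        per_cluster = [
            (assigned[dense == g] == g).mean() for g in range(len(groups))
        ]
        return float(np.mean(per_cluster))

    rows = []
    for n_pc in pc_grid:
        n_pc = int(min(n_pc, scores.shape[1]))
        obs = reassignment(labels, n_pc)
        null = [reassignment(rng.permutation(labels), n_pc) for _ in range(n_sim)]
        rows.append({"n_pc": n_pc, "observed": obs, "null_mean": float(np.mean(null)),
                     "a_score": obs - float(np.mean(null))})
    curve = pd.DataFrame(rows)
    best = int(curve.loc[curve["a_score"].idxmax(), "n_pc"])
    return curve, best


# ---------------------------------------------------------------------------
# supplementary projection
# ---------------------------------------------------------------------------

def project_supplementary(model: DapcModel, ds_new: GenotypeDataset) -> pd.DataFrame:
    """Project new individuals through the training PCA + DA loadings.

    Centering uses the *training* column means; alleles unseen in training
    contribute zero columns; fully missing calls fall back to the training
    mean (landing at the training centroid for that locus).  No refitting.
    Returns assignments, discriminant coordinates and membership rows.
    """
    basis = model.basis
    if basis is None:
        raise ValueError("model carries no PCA basis; fit through dapc_fit")
    shared = basis.loci & set(ds_new.loci)
    if not shared:
        raise ValueError("supplementary data share no locus with the training set")
    X, _, miss, _ = _allele_count_matrix(ds_new, columns=basis.columns)
    X = np.where(miss, basis.col_means[None, :], X)
    if basis.scale is not None:
        X = X / basis.scale
        means = basis.col_means / basis.scale
    else:
        means = basis.col_means
    scores = (X - means) @ basis.components
    coords = scores[:, : model.n_pc] @ model.da_vectors
    d2 = ((coords[:, None, :] - model.centroids[None]) ** 2).sum(axis=2)
    assigned = np.argmin(d2, axis=1)
    membership = _membership_from_coords(coords, model.centroids)
    out = pd.DataFrame({"assigned_cluster": assigned}, index=ds_new.individuals)
    for j in range(coords.shape[1]):
        out[f"LD{j + 1}"] = coords[:, j]
    for g in range(model.k):
        out[f"membership_{g}"] = membership[:, g]
    return out


# ---------------------------------------------------------------------------
# metagroup repeatability across replicate runs
# ---------------------------------------------------------------------------

@dataclass
class MetagroupSpec:
    metagroup_of_cluster: dict
    repeatability: dict          # metagroup -> mean score over replicates
    n_runs: int
    merges_credited: int = 0


def metagroup_repeatability(ref_labels: np.ndarray, metagroup_map: dict,
                            replicate_labels: list[np.ndarray],
                            merge_threshold: float = 0.9) -> MetagroupSpec:
    """Stability of reference metagroups across replicate clusterings.

    Every replicate cluster is mapped to the reference metagroup holding the
    plurality of its members (ties resolved toward the largest reference
    metagroup, with a warning).  The score of metagroup M in one replicate
    is the fraction of M's individuals whose replicate cluster maps to M;
    when at least ``merge_threshold`` of M travels together into one other
    metagroup, those individuals are credited as repeatable (merge, flagged).
    """
    ref_labels = np.asarray(ref_labels)
    unmapped = set(np.unique(ref_labels)) - set(metagroup_map)
    if unmapped:
        raise ValueError(f"reference clusters without metagroup: {sorted(unmapped)}")
    ref_mg = np.array([metagroup_map[c] for c in ref_labels], dtype=object)
    mg_names, mg_sizes = np.unique(ref_mg, return_counts=True)
    size_of = dict(zip(mg_names, mg_sizes))
    scores: dict[str, list[float]] = {m: [] for m in mg_names}
    merges = 0
    for rep in replicate_labels:
        rep = np.asarray(rep)
        if rep.shape != ref_labels.shape:
            raise ValueError("replicate run covers a different individual set")
        rep_to_mg = {}
        for c in np.unique(rep):
            members = ref_mg[rep == c]
            cand, cnt = np.unique(members, return_counts=True)
            top = cnt.max()
            leaders = [m for m, n_ in zip(cand, cnt) if n_ == top]
            if len(leaders) > 1:
                leaders.sort(key=lambda m: (-size_of[m], str(m)))
                warnings.warn(
                    f"plurality tie for replicate cluster {c}: kept {leaders[0]}"
                )
            rep_to_mg[c] = leaders[0]
        rep_mg = np.array([rep_to_mg[c] for c in rep], dtype=object)
        for m in mg_names:
            mask = ref_mg == m
            stay = float((rep_mg[mask] == m).mean())
            score = stay
            if stay < 1.0:
                others, counts = np.unique(rep_mg[mask][rep_mg[mask] != m],
                                           return_counts=True)
                if len(others):
                    j = int(np.argmax(counts))
                    frac_other = counts[j] / mask.sum()
                    if frac_other >= merge_threshold:
                        score = stay + frac_other
                        merges += 1
            scores[m].append(min(1.0, score))
    return MetagroupSpec(
        metagroup_of_cluster=dict(metagroup_map),
        repeatability={m: float(np.mean(v)) for m, v in scores.items()},
        n_runs=len(replicate_labels),
        merges_credited=merges,
    )


# ---------------------------------------------------------------------------
# one-call pipeline
# ---------------------------------------------------------------------------

def dapc_fit(ds: GenotypeDataset, k: int | None = None, k_max: int = 40,
             n_repeats: int = 4, n_pc: int | None = None, seed: int | None = None,
             a_score_sims: int = 6, scale: bool = False) -> tuple[DapcModel, KSelection | None]:
    """Encode, reduce, pick K (unless given), pick n_pc by a-score, fit."""
    scores, basis = encode_and_reduce(ds, scale=scale)
    k_max = min(k_max, ds.n_individuals - 1)
    selection = None
    if k is None:
        selection = select_k(scores, k_max=k_max, n_repeats=n_repeats, seed=seed)
        k = selection.suggested_k
        labels = selection.labels[k]
    else:
        rng = np.random.default_rng(seed)
        if k == 1:
            raise ValueError("DAPC needs K >= 2")
        labels = _best_kmeans(scores, k, n_repeats, rng, None).labels_
    if n_pc is None:
        _, n_pc = optimize_a_score(scores, labels, n_sim=a_score_sims, seed=seed)
    model = fit_discriminants(scores, labels, n_pc, basis=basis)
    model.seed = seed
    if selection is not None:
        model.bic_curve = selection.bic
    return model, selection
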