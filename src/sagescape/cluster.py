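"""Bootstrap-seeded K-means, within-cluster hierarchies, and sample PCA.

Seeding follows the bootstrap refinement of Bradley & Fayyad: S small
subsamples are each clustered with K-means, the resulting S*K candidate
centroids are pooled, K-means is run over the pooled candidates once per
candidate solution as the initialization, and the solution with the
smallest distortion over the candidate set becomes the initial seeds for
the final run on the full data. Rows are median-centered and scaled to
unit norm before clustering; each final cluster gets an average-linkage
dendrogram on correlation distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import cdist, squareform
from sklearn.decomposition import PCA as _SkPCA
from sklearn.metrics import adjusted_rand_score


@dataclass
class ClusterResult:
    assignment: dict[str, int]  # transcript -> label in 1..K
    centroids: pd.DataFrame  # K x samples
    within_ss: float
    K: int
    S: int
    dendrograms: dict[int, "Dendrogram"] = field(default_factory=dict)
    run_agreement: list[float] = field(default_factory=list)  # pairwise ARI of duplicated runs

    def labels(self, index: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[t] for t in index])

    def members(self, k: int) -> list[str]:
        return [t for t, c in self.assignment.items() if c == k]


@dataclass
class Dendrogram:
    leaves: list[str]
    linkage: np.ndarray | None  # scipy linkage matrix; None for singletons

    def to_newick(self) -> str:
        if self.linkage is None or len(self.leaves) == 1:
            return f"{self.leaves[0]};"
        return _linkage_to_newick(self.linkage, self.leaves)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # features x components


def adjust_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Median-center each row, then scale it to unit Euclidean norm.

    Rows with zero norm after centering (constant rows) are dropped with a
    warning. Idempotent: adjusted rows have median ~0 only in the odd-n
    case, but re-adjustment changes nothing beyond 1e-9 for typical data;
    the guarantee actually asserted is unit row norms.
    """
    x = values.to_numpy(dtype=float)
    centered = x - np.median(x, axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    keep = norms > 1e-12
    if not keep.all():
        dropped = list(values.index[~keep])
        warnings.warn(f"dropped {len(dropped)} constant row(s): {dropped[:5]}...")
    out = centered[keep] / norms[keep, None]
    return pd.DataFrame(out, index=values.index[keep], columns=values.columns)


def _distortion(x: np.ndarray, centers: np.ndarray) -> float:
    return float(np.min(cdist(x, centers, "sqeuclidean"), axis=1).sum())


def lloyd(
    x: np.ndarray,
    centers: np.ndarray,
    rng: np.random.Generator,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Plain Lloyd iteration with farthest-point repair of empty clusters.

    Asserts the objective is non-increasing across iterations. Returns
    (centers, labels, within-cluster sum of squares).
    """
    k = centers.shape[0]
    centers = centers.copy()
    prev_obj = np.inf
    labels = np.zeros(len(x), dtype=int)
    for _ in range(max_iter):
        d2 = cdist(x, centers, "sqeuclidean")
        labels = d2.argmin(axis=1)
        obj = float(d2[np.arange(len(x)), labels].sum())
        assert obj <= prev_obj + 1e-8, "K-means objective increased"
        prev_obj = obj
        new_centers = centers.copy()
        for j in range(k):
            mask = labels == j
            if mask.any():
                new_centers[j] = x[mask].mean(axis=0)
            else:  # re-seed an empty cluster from the farthest point
                far = d2.min(axis=1).argmax()
                new_centers[j] = x[far]
        shift = float(np.abs(new_centers - centers).max())
        centers = new_centers
        if shift < tol:
            break
    d2 = cdist(x, centers, "sqeuclidean")
    labels = d2.argmin(axis=1)
    wss = float(d2[np.arange(len(x)), labels].sum())
    return centers, labels, wss


def _random_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.choice(len(x), size=k, replace=False)
    return x[idx].copy()


def bf98_seed(
    x: np.ndarray,
    K: int,
    S: int,
    subsample_fraction: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Bootstrap-refined initial centroids (Bradley-Fayyad style).

    Each of S subsamples is clustered with randomly initialized K-means;
    the pooled S*K candidate centroids are then clustered with K-means
    started from every candidate solution in turn, and the centroid set
    with the smallest distortion over the candidate set is returned.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(x)
    m = min(n, int(round(subsample_fraction * n)))
    if m < K:
        raise ValueError(f"subsample size {m} smaller than K={K}")
    solutions = []
    for _ in range(S):
        sub = x[rng.choice(n, size=m, replace=False)]
        centers, _, _ = lloyd(sub, _random_init(sub, K, rng), rng)
        solutions.append(centers)
    candidates = np.vstack(solutions)
    best, best_obj = None, np.inf
    for init in solutions:
        centers, _, _ = lloyd(candidates, init, rng)
        obj = _distortion(candidates, centers)
        if obj < best_obj:
            best, best_obj = centers, obj
    return best


def kmeans_bf98(
    adjusted: pd.DataFrame,
    K: int = 10,
    S: int = 400,
    seed: int = 0,
    n_final_runs: int = 2,
    subsample_fraction: float = 0.1,
) -> ClusterResult:
    """Final K-means from bootstrap-refined seeds, with duplicated runs.

    Executes ``n_final_runs`` independent seeding+clustering runs, reports
    pairwise run agreement (adjusted Rand index), and returns the run with
    the smallest distortion. Labels are 1..K.
    """
    x = adjusted.to_numpy(dtype=float)
    if len(x) < K:
        raise ValueError(f"K={K} exceeds number of rows {len(x)}")
    runs = []
    for r in range(n_final_runs):
        rng = np.random.default_rng((seed, r))
        seeds = bf98_seed(x, K, S, subsample_fraction, rng)
        centers, labels, wss = lloyd(x, seeds, rng)
        runs.append((wss, labels, centers))
    agreement = [
        float(adjusted_rand_score(runs[i][1], runs[j][1]))
        for i in range(len(runs))
        for j in range(i + 1, len(runs))
    ]
    wss, labels, centers = min(runs, key=lambda t: t[0])
    assignment = {t: int(l) + 1 for t, l in zip(adjusted.index, labels)}
    result = ClusterResult(
        assignment=assignment,
        centroids=pd.DataFrame(centers, index=range(1, K + 1), columns=adjusted.columns),
        within_ss=wss,
        K=K,
        S=S,
        run_agreement=agreement,
    )
    for k in range(1, K + 1):
        members = result.members(k)
        if members:
            result.dendrograms[k] = hclust_within(members, adjusted)
    return result


def hclust_within(members: Sequence[str], adjusted: pd.DataFrame) -> Dendrogram:
    """Average-linkage dendrogram on 1 - Pearson correlation distance."""
    members = list(members)
    if len(members) == 1:
        return Dendrogram(leaves=members, linkage=None)
    x = adjusted.loc[members].to_numpy(dtype=float)
    d = 1.0 - np.corrcoef(x)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # symmetrize fp noise
    link = average(squareform(d, checks=False))
    from scipy.cluster.hierarchy import leaves_list

    order = leaves_list(link)
    return Dendrogram(leaves=[members[i] for i in order], linkage=link)


def _linkage_to_newick(link: np.ndarray, leaves_in_order: list[str]) -> str:
    # leaves_in_order is the dendrogram leaf ordering; newick needs original indexing
    from scipy.cluster.hierarchy import leaves_list

    order = leaves_list(link)
    names = [None] * len(order)
    for pos, idx in enumerate(order):
        names[idx] = leaves_in_order[pos]
    n = len(names)
    nodes: dict[int, tuple[str, float]] = {i: (names[i], 0.0) for i in range(n)}
    for i, (a, b, h, _) in enumerate(link):
        sa, ha = nodes[int(a)]
        sb, hb = nodes[int(b)]
        nodes[n + i] = (f"({sa}:{h - ha:.6g},{sb}:{h - hb:.6g})", float(h))
    return nodes[n + len(link) - 1][0] + ";"


def pca(log2_values: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """Column-mean-centered SVD of samples (columns are samples)."""
    if log2_values.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples")
    xt = log2_values.to_numpy(dtype=float).T  # samples x features
    n_components = min(n_components, min(xt.shape))
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(xt)
    comps = [f"PC{i+1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=log2_values.columns, columns=comps),
        explained_variance_ratio=model.explained_variance_ratio_,
        loadings=pd.DataFrame(model.components_.T, index=log2_values.index, columns=comps),
    )


def recompute_excluding(
    log2_values: pd.DataFrame, exclude: Sequence[str], n_components: int = 2
) -> PCAResult:
    """Drop named samples and refit the PCA on the remainder."""
    keep = [c for c in log2_values.columns if c not in set(exclude)]
    if len(keep) < 2:
        raise ValueError("cannot exclude all but one sample")
    return pca(log2_values[keep], n_components)


def sweep(
    adjusted: pd.DataFrame,
    K_values: Sequence[int],
    S_values: Sequence[int],
    seed: int = 0,
    subsample_fraction: float = 0.1,
) -> pd.DataFrame:
    """Model-selection grid: within-cluster SS and duplicated-run stability per (K, S)."""
    rows = []
    for K in K_values:
        for S in S_values:
            res = kmeans_bf98(adjusted, K=K, S=S, seed=seed, subsample_fraction=subsample_fraction)
            rows.append(
                {"K": K, "S": S, "within_ss": res.within_ss, "stability_ari": min(res.run_agreement)}
            )
    return pd.DataFrame(rows)
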