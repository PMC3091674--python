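"""Temporal clustering of expression profiles.

Genes with a large dynamic range (max - min of log2 expression strictly
above a cutoff) are clustered by k-means under the correlation distance
d(x, y) = 1 - Pearson r(x, y).  Profiles are centred and scaled to unit
norm per gene, after which maximizing within-cluster correlation equals
spherical k-means on the normalized vectors: the centroid step that
maximizes the summed correlation of a cluster is the renormalized mean
of its members, so the Lloyd objective (total correlation distance) is
non-increasing.  Correlation distance makes assignments invariant to
per-gene shifts and positive rescalings.

Cluster/annotation enrichment reuses the hypergeometric upper tail and
adds a Benjamini-Hochberg adjustment across all tested pairs.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .binding import overlap_pvalue

_MAX_ITER = 300


def select_variable_genes(expr: pd.DataFrame, min_range: float = 6.0) -> list:
    """Genes whose log2 range (max - min over timepoints) exceeds ``min_range``.

    The inequality is strict; missing values are ignored when taking the
    extremes, and all-missing genes are never selected.
    """
    values = expr.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        rng = np.nanmax(values, axis=1) - np.nanmin(values, axis=1)
    keep = np.where(np.isnan(rng), False, rng > min_range)
    return list(expr.index[keep])


def _normalize_rows(X: np.ndarray) -> np.ndarray:
    centred = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1, keepdims=True)
    return centred / norms


@dataclasses.dataclass
class ClusterResult:
    labels: pd.Series             # gene -> cluster id in 1..k
    centroids: pd.DataFrame       # cluster id x feature (mean member profile)
    k: int
    seed: int
    restarts: int
    objective: float              # final sum of correlation distances
    objective_trace: list         # per-iteration objective of the best restart
    n_iter: int


def kmeans_correlation(
    profiles: pd.DataFrame,
    k: int,
    seed: int = 0,
    restarts: int = 20,
) -> ClusterResult:
    """Lloyd k-means under correlation distance, best of ``restarts`` inits.

    Deterministic given ``seed``.  Zero-variance profiles cannot be
    correlated with anything and are rejected up front, naming the
    offending genes; ``k`` may not exceed the number of genes.
    """
    X = profiles.to_numpy(dtype=float)
    n = X.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} must lie in 1..{n} (number of genes)")
    sds = X.std(axis=1)
    if np.any(sds == 0):
        bad = list(profiles.index[sds == 0])
        raise ValueError(f"zero-variance profiles cannot be clustered: {bad}")
    Xn = _normalize_rows(X)
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, list, int] | None = None
    for _ in range(max(1, restarts)):
        centroids = Xn[rng.choice(n, size=k, replace=False)]
        labels = np.full(n, -1)
        trace: list[float] = []
        for it in range(_MAX_ITER):
            sims = Xn @ centroids.T           # cosine == Pearson r after normalizing
            new_labels = np.argmax(sims, axis=1)
            # re-seed empty clusters at the point farthest from its centroid
            for c in range(k):
                if not np.any(new_labels == c):
                    dist_own = 1.0 - sims[np.arange(n), new_labels]
                    far = int(np.argmax(dist_own))
                    new_labels[far] = c
                    centroids[c] = Xn[far]
                    sims[far, c] = 1.0
            objective = float(np.sum(1.0 - sims[np.arange(n), new_labels]))
            trace.append(objective)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            means = np.zeros((k, X.shape[1]))
            for c in range(k):
                means[c] = Xn[labels == c].mean(axis=0)
            norms = np.linalg.norm(means, axis=1, keepdims=True)
            norms[norms == 0] = 1.0           # degenerate: members cancel exactly
            centroids = means / norms
        if best is None or trace[-1] < best[0]:
            best = (trace[-1], labels.copy(), trace, it + 1)

    objective, labels, trace, n_iter = best
    centroid_profiles = pd.DataFrame(
        [X[labels == c].mean(axis=0) for c in range(k)],
        index=pd.RangeIndex(1, k + 1, name="cluster"),
        columns=profiles.columns,
    )
    return ClusterResult(
        labels=pd.Series(labels + 1, index=profiles.index, name="cluster"),
        centroids=centroid_profiles,
        k=k,
        seed=seed,
        restarts=restarts,
        objective=objective,
        objective_trace=trace,
        n_iter=n_iter,
    )


def annotation_enrichment(
    labels: pd.Series,
    annotation_map: pd.DataFrame,
    universe,
) -> pd.DataFrame:
    """Hypergeometric enrichment of each (cluster, category) pair.

    ``annotation_map`` is a two-column frame (gene, category).  The test
    universe is user-declared; categories with no member inside it are
    skipped with a warning.  Raw p-values are adjusted across all
    tested pairs by Benjamini-Hochberg.
    """
    if list(annotation_map.columns[:2]) != ["gene", "category"]:
        annotation_map = annotation_map.rename(
            columns=dict(zip(annotation_map.columns[:2], ["gene", "category"]))
        )
    universe = set(universe)
    rows = []
    for category, members in annotation_map.groupby("category")["gene"]:
        cat_genes = set(members) & universe
        if not cat_genes:
            warnings.warn(f"category {category!r} has no genes in the universe; skipped")
            continue
        for cluster, genes in labels.groupby(labels):
            cluster_genes = set(genes.index) & universe
            overlap = len(cluster_genes & cat_genes)
            p = overlap_pvalue(cluster_genes, cat_genes, len(universe))
            rows.append((cluster, category, len(cluster_genes), len(cat_genes), overlap, p))
    result = pd.DataFrame(
        rows, columns=["cluster", "category", "cluster_size", "category_size", "overlap", "p"]
    )
    if len(result):
        result["q"] = multipletests(result["p"], method="fdr_bh")[1]
    else:
        result["q"] = pd.Series(dtype=float)
    return result
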