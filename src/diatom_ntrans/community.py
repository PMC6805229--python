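"""Community structure: zero-adjusted dissimilarities, Ward clustering
with silhouette-based k selection, BIOENV subset selection and
environmental PCA.

The zero-adjusted Bray-Curtis/Sørensen coefficient appends a dummy
feature with a fixed positive value to every sample before computing
Bray-Curtis, so that two samples in which nothing was detected are
identical (distance 0) instead of undefined, and sparse samples are
pulled together smoothly.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric site x site dissimilarity with its construction recipe."""

    values: pd.DataFrame
    metric: str                 # sorensen_pa | braycurtis_abund | euclidean_env
    dummy: float | None = None

    def condensed(self) -> np.ndarray:
        return squareform(self.values.to_numpy(), checks=False)

    def validate(self) -> "DistanceMatrix":
        a = self.values.to_numpy()
        if not np.allclose(a, a.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(a), 0.0):
            raise ValueError("distance matrix diagonal not zero")
        if self.metric in ("sorensen_pa", "braycurtis_abund") and (a > 1 + 1e-12).any():
            raise ValueError("community dissimilarity exceeds 1")
        return self


@dataclasses.dataclass
class ClusterSolution:
    labels: pd.Series           # site -> 1..k
    k: int
    linkage: str
    silhouette: pd.Series | None = None   # mean width per candidate k


def zero_adjusted_dissimilarity(
    table: pd.DataFrame, metric: str = "braycurtis_abund", dummy: float | None = None
) -> DistanceMatrix:
    """Zero-adjusted Bray-Curtis (abundance) or Sørensen (binary) matrix.

    ``table`` is feature x sample; distances are between samples:
    ``d(x, y) = sum|x_i - y_i| / (sum(x_i + y_i) + 2*dummy)``.
    The Sørensen variant binarizes the table first (Bray-Curtis on
    presence-absence is one minus the Sørensen similarity) and defaults
    to a dummy of 1 — a dummy clade present everywhere; on the abundance
    scale the dummy defaults to the smallest nonzero entry.
    """
    x = table.to_numpy(dtype=float).T        # samples x features
    if (x < 0).any():
        raise ValueError("negative abundances")
    if metric == "sorensen_pa":
        x = (x > 0).astype(float)
        if dummy is None:
            dummy = 1.0
    elif metric == "braycurtis_abund":
        if dummy is None:
            nz = x[x > 0]
            dummy = float(nz.min()) if nz.size else 1.0
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if dummy <= 0:
        raise ValueError("dummy must be positive")
    aug = np.hstack([x, np.full((x.shape[0], 1), dummy)])
    d = squareform(pdist(aug, metric="braycurtis"))
    values = pd.DataFrame(d, index=table.columns, columns=table.columns)
    return DistanceMatrix(values, metric, dummy).validate()


def euclidean_env_distance(env: pd.DataFrame, subset: list[str]) -> DistanceMatrix:
    """Euclidean distance on z-standardized environmental variables."""
    z = _standardize(env[subset])
    d = squareform(pdist(z.to_numpy(), metric="euclidean"))
    return DistanceMatrix(pd.DataFrame(d, index=env.index, columns=env.index),
                          "euclidean_env").validate()


def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    mu = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    return (df - mu) / sd.replace(0.0, 1.0)


def ward_cluster(d: DistanceMatrix, k: int) -> ClusterSolution:
    """Cut a Ward-linkage tree of the dissimilarity matrix at k groups.

    Ward linkage is applied to the dissimilarities directly (the update
    rule operates on squared distances, the usual generalization of
    Ward's minimum-variance criterion to non-Euclidean input).  Labels
    are renumbered 1..k in order of first appearance, so the solution is
    deterministic in the site order of ``d``.
    """
    n = len(d.values)
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")
    link = hierarchy.linkage(d.condensed(), method="ward")
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        labels[i] = relabel.setdefault(lab, len(relabel) + 1)
    return ClusterSolution(pd.Series(labels, index=d.values.index, name="cluster"),
                           k=k, linkage="ward")


def select_k(d: DistanceMatrix, k_range: range | list[int]) -> ClusterSolution:
    """Pick the cut level maximizing mean silhouette width on ``d``.

    Ties are broken toward the smaller k (parsimony).  The full
    silhouette profile over candidates is attached to the solution.
    """
    widths = {}
    best = None
    for k in sorted(k_range):
        sol = ward_cluster(d, k)
        if sol.labels.nunique() < 2:
            widths[k] = np.nan
            continue
        s = silhouette_score(d.values.to_numpy(), sol.labels.to_numpy(),
                             metric="precomputed")
        widths[k] = s
        if best is None or s > widths[best.k] + 1e-12:
            best = sol
    if best is None:
        raise ValueError("no candidate k produced >= 2 clusters")
    best.silhouette = pd.Series(widths, name="mean_silhouette").rename_axis("k")
    return best


def bioenv_select(
    env: pd.DataFrame, d_comm: DistanceMatrix,
    candidates: list[str] | None = None, max_subset_size: int | None = None,
    exhaustive_limit: int = 12,
) -> tuple[list[str], float, pd.DataFrame]:
    """BIOENV: the variable subset whose Euclidean distances best
    rank-correlate (Spearman) with the community dissimilarity.

    The search is exhaustive over all non-empty subsets of the candidate
    variables (constant variables are excluded up front).  With more
    than ``exhaustive_limit`` candidates the subset size is capped at
    that limit, with a warning.  Returns the best subset, its
    correlation, and the per-subset-size best results.
    """
    if candidates is None:
        candidates = [c for c in env.columns]
    env = env.loc[d_comm.values.index, candidates]
    usable = [c for c in candidates if env[c].nunique(dropna=True) > 1]
    if not usable:
        raise ValueError("all candidate variables are constant")
    max_size = len(usable)
    if len(usable) > exhaustive_limit:
        warnings.warn(
            f"{len(usable)} candidates: capping subset size at {exhaustive_limit}")
        max_size = exhaustive_limit
    if max_subset_size is not None:
        max_size = min(max_size, max_subset_size)

    z = _standardize(env[usable]).to_numpy()
    target = d_comm.condensed()
    target_rank = stats.rankdata(target)

    best_subset, best_rho = None, -np.inf
    per_size: dict[int, tuple[float, tuple[str, ...]]] = {}
    for size in range(1, max_size + 1):
        for cols in itertools.combinations(range(len(usable)), size):
            dv = pdist(z[:, cols], metric="euclidean")
            rho = _spearman_vs_ranked(dv, target_rank)
            names = tuple(usable[i] for i in cols)
            if size not in per_size or rho > per_size[size][0] + 1e-15:
                per_size[size] = (rho, names)
            if rho > best_rho + 1e-15:   # ties keep the smaller/earlier subset
                best_rho, best_subset = rho, names
    profile = pd.DataFrame(
        [(s, r, ",".join(n)) for s, (r, n) in sorted(per_size.items())],
        columns=["size", "rho", "variables"]).set_index("size")
    return list(best_subset), float(best_rho), profile


def _spearman_vs_ranked(x: np.ndarray, y_rank: np.ndarray) -> float:
    xr = stats.rankdata(x)
    xc = xr - xr.mean()
    yc = y_rank - y_rank.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return np.nan
    return float((xc * yc).sum() / denom)


@dataclasses.dataclass
class PCAResult:
    coordinates: pd.DataFrame      # site x PC (first two by default use)
    loadings: pd.DataFrame         # variable x PC
    variance_explained: pd.Series  # % per PC
    clusters: pd.Series | None


def env_pca(
    env: pd.DataFrame, subset: list[str], clusters: ClusterSolution | None = None
) -> PCAResult:
    """PCA of the standardized environmental subset, with cluster labels
    attached for plotting cluster x environment structure."""
    if not subset:
        raise ValueError("empty variable subset")
    sub = env[subset].dropna(axis=0)
    if len(sub) < 3:
        raise ValueError("need >= 3 complete sites")
    z = _standardize(sub)
    n_comp = min(len(subset), len(sub) - 1)
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(z.to_numpy())
    pcs = [f"PC{i + 1}" for i in range(n_comp)]
    labels = None
    if clusters is not None:
        labels = clusters.labels.reindex(sub.index)
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=sub.index, columns=pcs),
        loadings=pd.DataFrame(pca.components_.T, index=subset, columns=pcs),
        variance_explained=pd.Series(pca.explained_variance_ratio_ * 100,
                                     index=pcs, name="pct_variance"),
        clusters=labels)
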