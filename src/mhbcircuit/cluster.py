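"""Co-regulation clustering of SDE genes and cluster-phenotype correlation.

SDE genes are partitioned by K-means on their per-sample normalized log2
expression (Euclidean distance, K-means++ initialization, best of several
restarts).  Rows are mean-centered by default so distance reflects the
shape of the response rather than absolute expression.  The number of
clusters is chosen by evaluating every K in a range (2-12 by default) and
keeping the K with the largest mean silhouette coefficient, ties going to
the smaller K.

Cluster profiles are per-condition mean log2 fold changes of member genes
relative to the host-alone baseline condition; the profile of a designated
cluster can be tested against a phenotype vector (percent mycorrhization)
by comparing its Pearson correlation to the distribution of the other
clusters' correlations under a normal reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io import CONDITIONS, IntegrityError, StudyDesign

DEFAULT_K_RANGE = (2, 12)
DEFAULT_RESTARTS = 25


@dataclass(frozen=True)
class ClusterModel:
    """A fitted co-regulation clustering.

    Attributes
    ----------
    K : selected number of clusters.
    assignment : gene id -> cluster index (0-based).
    centroids : K x samples array in the clustering feature space.
    silhouette_by_k : mean silhouette coefficient per evaluated K.
    profiles : cluster x condition mean log2 fold change vs baseline
        (filled by :func:`cluster_profiles`; baseline column is 0).
    """

    K: int
    assignment: pd.Series
    centroids: np.ndarray
    silhouette_by_k: Dict[int, float]
    profiles: pd.DataFrame | None = None

    def members(self, cluster: int) -> list[str]:
        s = self.assignment
        return list(s.index[s == cluster])

    def sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()


def prepare_features(matrix: pd.DataFrame, scale: str = "center") -> pd.DataFrame:
    """Row-wise feature scaling for clustering.

    ``"center"`` subtracts each gene's mean (default), ``"zscore"`` also
    divides by the row SD, ``"none"`` leaves values untouched.
    """
    if scale == "none":
        return matrix
    centered = matrix.sub(matrix.mean(axis=1), axis=0)
    if scale == "center":
        return centered
    if scale == "zscore":
        sd = matrix.std(axis=1, ddof=0).replace(0.0, 1.0)
        return centered.div(sd, axis=0)
    raise ValueError("scale must be 'center', 'zscore' or 'none'")


def kmeans_fit(
    matrix: pd.DataFrame,
    k: int,
    seed: int | None = None,
    n_restarts: int = DEFAULT_RESTARTS,
) -> Tuple[pd.Series, np.ndarray]:
    """K-means on gene row-vectors; best of ``n_restarts`` by within-cluster
    sum of squares.  Returns (assignment, centroids)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(matrix) < k:
        raise ValueError("fewer genes than clusters")
    km = KMeans(
        n_clusters=k, n_init=n_restarts, random_state=_as_sklearn_seed(seed)
    ).fit(matrix.to_numpy(dtype=float))
    assignment = pd.Series(km.labels_, index=matrix.index, name="cluster")
    return assignment, km.cluster_centers_


def _as_sklearn_seed(seed: int | None) -> int | None:
    if seed is None:
        return None
    return int(np.uint32(seed))


def select_k_silhouette(
    matrix: pd.DataFrame,
    k_min: int = DEFAULT_K_RANGE[0],
    k_max: int = DEFAULT_K_RANGE[1],
    seed: int | None = None,
    n_restarts: int = DEFAULT_RESTARTS,
    scale: str = "center",
) -> ClusterModel:
    """Fit K-means for each K in [k_min, k_max] and keep the silhouette argmax.

    The silhouette is the mean over genes of the standard cohesion/
    separation score under Euclidean distance; ties break toward smaller K.
    """
    if k_min < 2 or k_max < k_min:
        raise ValueError("need 2 <= k_min <= k_max")
    X = prepare_features(matrix, scale=scale)
    n = len(X)
    if k_max >= n:
        warnings.warn(
            f"k_max {k_max} >= number of genes {n}; truncating to {n - 1}",
            stacklevel=2,
        )
        k_max = n - 1
    best: ClusterModel | None = None
    sil: Dict[int, float] = {}
    fits: Dict[int, Tuple[pd.Series, np.ndarray]] = {}
    for k in range(k_min, k_max + 1):
        assignment, centroids = kmeans_fit(X, k, seed=seed, n_restarts=n_restarts)
        if assignment.nunique() < 2:
            sil[k] = -1.0
        else:
            sil[k] = float(
                silhouette_score(X.to_numpy(dtype=float), assignment.to_numpy())
            )
        fits[k] = (assignment, centroids)
    k_best = max(sorted(sil), key=lambda k: sil[k])  # ties -> smaller K
    assignment, centroids = fits[k_best]
    return ClusterModel(k_best, assignment, centroids, sil)


def cluster_profiles(
    model: ClusterModel,
    matrix: pd.DataFrame,
    design: StudyDesign,
) -> pd.DataFrame:
    """Cluster x condition mean log2 fold change vs the baseline condition.

    Each gene's per-sample values are first referenced to its own mean in
    the baseline (host-alone) samples; profiles then average over member
    genes and replicates.  The baseline column is identically 0.
    Invariant to gene order and replicate order.
    """
    cond = design.condition
    baseline_samples = design.samples_of("baseline")
    if not baseline_samples:
        raise IntegrityError("design has no baseline condition")
    genes = model.assignment.index
    sub = matrix.loc[genes]
    fc = sub.sub(sub[baseline_samples].mean(axis=1), axis=0)
    rows = {}
    for c in sorted(model.assignment.unique()):
        members = model.members(c)
        rows[c] = {
            condition: float(
                fc.loc[members, design.samples_of(condition)].to_numpy().mean()
            )
            for condition in CONDITIONS
        }
    profiles = pd.DataFrame.from_dict(rows, orient="index")[list(CONDITIONS)]
    profiles.index.name = "cluster"
    return profiles


def with_profiles(
    model: ClusterModel, matrix: pd.DataFrame, design: StudyDesign
) -> ClusterModel:
    """Return a copy of the model carrying its condition profiles."""
    from dataclasses import replace

    return replace(model, profiles=cluster_profiles(model, matrix, design))


def normal_reference_p(r_target: float, other_rs: Iterable[float]) -> Tuple[float, float]:
    """z-score and one-tailed upper normal p for one correlation against the
    empirical distribution of the others: z = (r - mean) / sd(ddof=1)."""
    others = np.asarray(list(other_rs), dtype=float)
    z = (r_target - others.mean()) / others.std(ddof=1)
    return float(z), float(sps.norm.sf(z))


def profile_phenotype_correlation(
    profiles: pd.DataFrame,
    phenotype: pd.Series,
    target_cluster: int,
) -> Tuple[pd.Series, float, float]:
    """Pearson correlation of each cluster's condition profile with a
    phenotype vector, and a normal-reference significance for one cluster.

    The target cluster's correlation r is compared against the other
    clusters' correlations via z = (r_target - mean(others)) / sd(others)
    and a one-tailed upper normal p-value (the claim being tested is that
    the target tracks the phenotype more closely than any other cluster).
    Zero-variance profiles yield an undefined r (NaN) and are excluded from
    the reference set.
    """
    if len(profiles) < 3:
        raise ValueError("need >= 3 clusters to form a reference distribution")
    phen = phenotype.reindex(profiles.columns)
    if phen.isna().any():
        raise IntegrityError("phenotype vector does not cover the conditions")
    y = phen.to_numpy(dtype=float)
    r = {}
    for c, row in profiles.iterrows():
        x = row.to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            r[c] = np.nan
        else:
            r[c] = float(np.corrcoef(x, y)[0, 1])
    r = pd.Series(r, name="pcc")
    others = r.drop(index=target_cluster).dropna()
    if len(others) < 2 or np.isnan(r[target_cluster]):
        return r, float("nan"), float("nan")
    z, p = normal_reference_p(float(r[target_cluster]), others)
    return r, z, p


def profile_correlation_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between cluster condition profiles."""
    return profiles.T.corr(method="pearson")


def most_anticorrelated_pair(profiles: pd.DataFrame) -> Tuple[int, int, float]:
    """The pair of clusters with the most negative profile correlation."""
    corr = profile_correlation_matrix(profiles)
    best = (None, None, np.inf)
    for i in corr.index:
        for j in corr.index:
            if i < j and corr.loc[i, j] < best[2]:
                best = (i, j, float(corr.loc[i, j]))
    return best
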