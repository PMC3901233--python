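"""Ordination and clustering of sample fingerprints.

Classical (Torgerson) multidimensional scaling embeds a dissimilarity
matrix into a low-dimensional configuration whose pairwise Euclidean
distances best approximate the input in the least-squares sense of the
double-centered Gram matrix. For exactly-Euclidean input the embedding is
exact (up to rotation/reflection); for general dissimilarities such as
the weighted Manhattan statistic, axes with negative eigenvalues signal
the non-Euclidean part and are dropped with a report.

Clustering operates on max-standardized abundances: each feature divided
by its maximum over the selected samples, so every feature lies in [0, 1]
and contributes comparably regardless of raw intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .dataset import Dataset

LINKAGES = ("average", "complete", "single")


@dataclass
class MDSResult:
    coordinates: pd.DataFrame      # samples x retained dims, by descending eigenvalue
    eigenvalues: np.ndarray        # all eigenvalues, descending
    n_negative: int                # count of negative eigenvalues (axes dropped)


def classical_mds(distances: pd.DataFrame, dims: int = 2) -> MDSResult:
    """Torgerson scaling of a symmetric dissimilarity matrix.

    Double-centers -0.5 * D^2, eigendecomposes, and keeps the ``dims``
    leading axes with positive eigenvalues. Missing entries are an error:
    impute or subset before embedding.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(D).any():
        raise ValueError("distance matrix has missing entries; impute or subset first")
    if dims < 1:
        raise ValueError("dims must be >= 1")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    # symmetrize against round-off before eigh
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_negative = int(np.sum(eigval < -1e-12 * max(1.0, abs(eigval[0]))))
    usable = min(dims, int(np.sum(eigval > 1e-12 * max(1.0, abs(eigval[0])))))
    coords = eigvec[:, :usable] * np.sqrt(eigval[:usable])
    index = distances.index if isinstance(distances, pd.DataFrame) else pd.RangeIndex(n)
    frame = pd.DataFrame(coords, index=index, columns=[f"dim{i + 1}" for i in range(usable)])
    return MDSResult(coordinates=frame, eigenvalues=eigval, n_negative=n_negative)


def mds_stress(distances, coordinates) -> float:
    """Raw stress: sum of squared discrepancies between input and embedded distances."""
    D = np.asarray(distances, dtype=float)
    emb = squareform(pdist(np.asarray(coordinates, dtype=float)))
    return float(np.sum((D - emb) ** 2) / 2.0)


def standardize_max(dataset: Dataset) -> pd.DataFrame:
    """Divide each feature by its maximum abundance over the selected samples.

    Result lies in [0, 1] with every retained feature attaining 1 somewhere.
    Features with no positive value carry no pattern and are dropped with
    a warning. Idempotent: standardizing twice changes nothing.
    """
    values = dataset.abundance
    maxima = values.max(axis=1, skipna=True)
    keep = maxima > 0
    if (~keep).any():
        warnings.warn(
            f"dropped {int((~keep).sum())} feature(s) with no positive value",
            stacklevel=2,
        )
    return values.loc[keep].div(maxima[keep], axis=0)


@dataclass
class KMeansResult:
    assignments: pd.Series         # sample_id -> cluster label (0..k-1)
    within_ss: float               # within-cluster sum of squares (inertia)
    centers: np.ndarray


def kmeans_cluster(
    standardized: pd.DataFrame,
    k: int,
    n_init: int = 10,
    seed: int = 0,
) -> KMeansResult:
    """K-means over samples (columns of the standardized matrix).

    Best of ``n_init`` k-means++ initializations with a fixed seed, so the
    same seed always returns the same assignment. Labels are arbitrary:
    compare partitions with :func:`adjusted_rand_index`, not label equality.
    """
    X = standardized.to_numpy(dtype=float).T  # samples as rows
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of samples {X.shape[0]}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if np.isnan(X).any():
        raise ValueError("standardized matrix has missing entries")
    model = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = model.fit_predict(X)
    return KMeansResult(
        assignments=pd.Series(labels, index=standardized.columns, name="cluster"),
        within_ss=float(model.inertia_),
        centers=model.cluster_centers_,
    )


@dataclass
class HierarchicalResult:
    assignments: pd.Series         # sample_id -> cluster label (1..k)
    merge_tree: np.ndarray         # scipy linkage matrix (n-1, 4)
    linkage: str


def hierarchical_cluster(
    data: pd.DataFrame,
    k: int,
    linkage: str = "average",
    precomputed: bool = False,
) -> HierarchicalResult:
    """Agglomerative clustering cut into ``k`` groups.

    ``data`` is either a standardized (features x samples) matrix — in
    which case Euclidean distances between sample columns are used — or,
    with ``precomputed=True``, a square distance matrix over samples.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if precomputed:
        D = np.asarray(data, dtype=float)
        if D.shape[0] != D.shape[1]:
            raise ValueError("precomputed distance matrix must be square")
        if np.isnan(D).any():
            raise ValueError("distance matrix has missing entries")
        condensed = squareform((D + D.T) / 2.0, checks=False)
        ids = data.index if isinstance(data, pd.DataFrame) else pd.RangeIndex(D.shape[0])
    else:
        X = data.to_numpy(dtype=float).T
        condensed = pdist(X, metric="euclidean")
        ids = data.columns
    if len(ids) < 2:
        raise ValueError("need at least 2 samples")
    Z = hierarchy.linkage(condensed, method=linkage)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return HierarchicalResult(
        assignments=pd.Series(labels, index=ids, name="cluster"),
        merge_tree=Z,
        linkage=linkage,
    )


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement: 1 identical, ~0 at chance."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(a, b))
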