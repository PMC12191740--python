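"""Latent-space reduction, 2-D embedding, and density clustering.

Learned cell representations are first reduced linearly (PCA on the
covariance spectrum), then projected to two dimensions with UMAP, and
finally grouped with HDBSCAN.  Points HDBSCAN leaves unassigned form an
explicit *background* stratum (label -1) rather than being discarded:
background carries its own classification metrics and may receive
annotation effort just like any named cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import HDBSCAN
from sklearn.neighbors import NearestNeighbors

from .synthdata import BACKGROUND, EmbeddingDataset


@dataclass(frozen=True)
class LinearReducer:
    """PCA projection fitted on centered data.

    Components are eigenvectors of the sample covariance matrix ordered by
    decreasing eigenvalue; each component's sign is fixed by making its
    largest-magnitude coordinate positive, so a refit on identical data is
    bit-identical.
    """

    mean: np.ndarray               # (D,)
    basis: np.ndarray              # (m, D), orthonormal rows
    explained_variance: np.ndarray  # (m,) eigenvalues
    total_variance: float

    @property
    def m(self) -> int:
        return self.basis.shape[0]

    @property
    def retained_variance(self) -> float:
        if self.total_variance == 0:
            return 1.0
        return float(self.explained_variance.sum() / self.total_variance)


@dataclass(frozen=True)
class PlanarEmbeddingParams:
    """UMAP settings for the 2-D latent-space view."""

    n_neighbors: int = 15
    min_dist: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if self.min_dist < 0:
            raise ValueError("min_dist must be nonnegative")


@dataclass
class ClusterModel:
    """2-D coordinates plus integer stratum labels (-1 = background)."""

    coords: np.ndarray   # (N, 2)
    labels: np.ndarray   # (N,) int, >= -1

    def __post_init__(self) -> None:
        if self.coords.shape[0] != self.labels.shape[0]:
            raise ValueError("coords and labels must have equal length")
        if self.labels.min(initial=BACKGROUND) < BACKGROUND:
            raise ValueError("labels must be >= -1")

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels >= 0].tolist())))

    @property
    def strata(self) -> list[int]:
        return sorted(set(self.labels.tolist()))


def default_min_cluster_size(n: int) -> int:
    return max(25, n // 200)


def fit_linear_reducer(
    features: np.ndarray,
    variance_target: float | None = None,
    n_components: int | None = None,
) -> LinearReducer:
    """Fit PCA, choosing the component count by either criterion.

    Exactly one of ``variance_target`` (smallest m whose retained variance
    meets the target) or ``n_components`` must be given.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("features must be an (N >= 2) x D matrix")
    if (variance_target is None) == (n_components is None):
        raise ValueError(
            "exactly one of variance_target / n_components must be given"
        )
    n, d = features.shape
    if variance_target is not None and not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must lie in (0, 1]")
    if n_components is not None and not 0 < n_components <= d:
        raise ValueError(f"n_components must lie in (0, {d}]")

    mean = features.mean(axis=0)
    centered = features - mean
    cov = centered.T @ centered / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    components = eigvecs[:, order].T  # rows are components

    # deterministic sign: largest-magnitude coordinate positive
    signs = np.sign(components[np.arange(d), np.abs(components).argmax(axis=1)])
    signs[signs == 0] = 1.0
    components = components * signs[:, None]

    total = float(eigvals.sum())
    if variance_target is not None:
        if total == 0:
            m = 1
        else:
            cumulative = np.cumsum(eigvals) / total
            m = int(np.searchsorted(cumulative, variance_target - 1e-12) + 1)
            m = min(m, d)
    else:
        m = int(n_components)

    return LinearReducer(
        mean=mean,
        basis=components[:m],
        explained_variance=eigvals[:m],
        total_variance=total,
    )


def reduce(reducer: LinearReducer, features: np.ndarray) -> np.ndarray:
    """Center and project features onto the fitted basis."""
    features = np.asarray(features, dtype=float)
    if features.shape[1] != reducer.mean.shape[0]:
        raise ValueError(
            f"feature dimension {features.shape[1]} does not match reducer "
            f"dimension {reducer.mean.shape[0]}"
        )
    return (features - reducer.mean) @ reducer.basis.T


def reduce_dataset(reducer: LinearReducer, dataset: EmbeddingDataset) -> EmbeddingDataset:
    """Copy of the dataset with features replaced by their PCA projection."""
    out = dataset.subset(np.ones(len(dataset), dtype=bool))
    out.features = reduce(reducer, dataset.features)
    return out


def embed_2d(reduced: np.ndarray, params: PlanarEmbeddingParams) -> np.ndarray:
    """Project reduced features to 2-D with UMAP (seeded, hence deterministic)."""
    import umap  # deferred: heavy import

    reduced = np.asarray(reduced, dtype=float)
    if reduced.shape[0] <= params.n_neighbors:
        raise ValueError(
            f"need more than n_neighbors={params.n_neighbors} points, "
            f"got {reduced.shape[0]}"
        )
    with warnings.catch_warnings():
        # seeded UMAP warns that it forces single-threaded execution
        warnings.simplefilter("ignore")
        model = umap.UMAP(
            n_components=2,
            n_neighbors=params.n_neighbors,
            min_dist=params.min_dist,
            random_state=params.seed,
        )
        coords = model.fit_transform(reduced)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("2-D embedding produced non-finite coordinates")
    return np.asarray(coords, dtype=float)


def cluster_2d(coords: np.ndarray, min_cluster_size: int | None = None) -> ClusterModel:
    """Density-cluster 2-D coordinates; low-density points become background."""
    coords = np.asarray(coords, dtype=float)
    if min_cluster_size is None:
        min_cluster_size = default_min_cluster_size(coords.shape[0])
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    if coords.shape[0] < min_cluster_size:
        raise ValueError(
            f"need at least min_cluster_size={min_cluster_size} points, "
            f"got {coords.shape[0]}"
        )
    if np.allclose(coords, coords[0]):
        # degenerate: all points identical; HDBSCAN cannot build a hierarchy
        return ClusterModel(
            coords=coords, labels=np.zeros(coords.shape[0], dtype=int)
        )
    labels = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(coords)
    return ClusterModel(coords=coords, labels=labels.astype(int))


@dataclass
class JointClustering:
    """Joint cluster analysis of the unlabeled-train + test latent space.

    ``stratum_map`` partitions the ids that were clustered; ids outside the
    joint set (e.g. the labeled training pool) are assigned the stratum of
    their nearest joint-clustered neighbor in the 2-D plane via ``assign``.
    """

    model: ClusterModel
    ids: np.ndarray
    stratum_map: dict[str, int]
    reducer: LinearReducer
    params: PlanarEmbeddingParams
    _umap_model: object = field(default=None, repr=False)

    def assign(self, features: np.ndarray) -> np.ndarray:
        """Map out-of-sample features to strata by nearest 2-D neighbor."""
        reduced = reduce(self.reducer, features)
        if self._umap_model is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                coords = self._umap_model.transform(reduced)
        else:
            coords = reduced[:, :2]
        nn = NearestNeighbors(n_neighbors=1).fit(self.model.coords)
        _, idx = nn.kneighbors(np.asarray(coords, dtype=float))
        return self.model.labels[idx[:, 0]]


def joint_cluster(
    unlabeled_train: EmbeddingDataset,
    test: EmbeddingDataset,
    reducer: LinearReducer,
    params: PlanarEmbeddingParams,
    min_cluster_size: int | None = None,
) -> JointClustering:
    """Cluster the joint unlabeled-train + test latent space.

    Both sets are reduced with the supplied PCA, embedded together, and
    density-clustered together; every joint id receives exactly one stratum
    (cluster index or background).
    """
    overlap = set(unlabeled_train.ids.tolist()) & set(test.ids.tolist())
    if overlap:
        raise ValueError(
            f"unlabeled-train and test id sets overlap ({len(overlap)} ids)"
        )
    if len(test) == 0:
        joint_ids = unlabeled_train.ids
        features = unlabeled_train.features
    else:
        joint_ids = np.concatenate([unlabeled_train.ids, test.ids])
        features = np.vstack([unlabeled_train.features, test.features])

    import umap

    reduced = reduce(reducer, features)
    if reduced.shape[0] <= params.n_neighbors:
        raise ValueError(
            f"need more than n_neighbors={params.n_neighbors} joint points"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        umap_model = umap.UMAP(
            n_components=2,
            n_neighbors=params.n_neighbors,
            min_dist=params.min_dist,
            random_state=params.seed,
        )
        coords = np.asarray(umap_model.fit_transform(reduced), dtype=float)
    model = cluster_2d(coords, min_cluster_size=min_cluster_size)
    stratum_map = dict(zip(joint_ids.tolist(), model.labels.tolist()))
    return JointClustering(
        model=model,
        ids=joint_ids,
        stratum_map=stratum_map,
        reducer=reducer,
        params=params,
        _umap_model=umap_model,
    )
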