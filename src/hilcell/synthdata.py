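"""Synthetic embedding datasets, labeling oracles, and synthetic cartridge images.

The generators emulate the data a circulating-tumor-cell (CTC) triage
pipeline consumes: clustered Gaussian embeddings with per-cluster class
mixtures (standing in for learned single-cell image representations) and
three-channel fluorescence cartridge tiles (DAPI / CK / CD45) with instance
masks.  Everything is deterministic given a seed, so the downstream
human-in-the-loop machinery can be exercised end to end without any
external download.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

POSITIVE = "positive"
NEGATIVE = "negative"
UNLABELED = "unlabeled"

BACKGROUND = -1

#: split tags an EmbeddingDataset row may carry
SPLITS = ("ssl", "train_labeled", "train_unlabeled", "test", "holdout")

#: cartridge tile geometry of the CellSearch-style scanner (rows, cols)
CARTRIDGE_SHAPE = (1036, 1384)


class BudgetExhaustedError(RuntimeError):
    """Raised when an oracle is queried beyond its per-loop budget."""


@dataclass(frozen=True)
class SyntheticLatentConfig:
    """Parameters of the clustered-Gaussian embedding generator.

    Each cluster is an isotropic unit-variance Gaussian blob in ``dim``
    dimensions whose positive (CTC) and negative class means are pulled
    apart by ``separability`` within-class standard deviations along a
    random unit direction.  ``separability = 0`` makes the two classes
    indistinguishable; values around 5 make them trivially separable.
    """

    n_clusters: int
    dim: int = 128
    points_per_cluster: tuple[int, ...] = ()
    class_mix: tuple[float, ...] = ()
    separability: tuple[float, ...] = ()
    background_fraction: float = 0.0
    noisy_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be a positive integer")
        if self.dim < 1:
            raise ValueError("dim must be a positive integer")
        for name in ("points_per_cluster", "class_mix", "separability"):
            values = getattr(self, name)
            if len(values) != self.n_clusters:
                raise ValueError(
                    f"{name} must have length n_clusters={self.n_clusters}, "
                    f"got {len(values)}"
                )
        if any(p < 1 for p in self.points_per_cluster):
            raise ValueError("points_per_cluster entries must be positive")
        if any(not 0.0 <= m <= 1.0 for m in self.class_mix):
            raise ValueError("class_mix entries must lie in [0, 1]")
        if any(s < 0 for s in self.separability):
            raise ValueError("separability entries must be nonnegative")
        for name in ("background_fraction", "noisy_fraction"):
            frac = getattr(self, name)
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class EmbeddingDataset:
    """One row per cell: id, feature vector, optional label / split tags."""

    ids: np.ndarray            # (N,) str
    features: np.ndarray       # (N, D) float
    labels: np.ndarray         # (N,) str in {positive, negative, unlabeled}
    true_cluster: np.ndarray   # (N,) int, BACKGROUND for off-cluster points
    noisy: np.ndarray          # (N,) bool
    split: np.ndarray          # (N,) str

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("features", "labels", "true_cluster", "noisy", "split"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match ids ({n})")
        if len(np.unique(self.ids)) != n:
            raise ValueError("ids must be unique")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")
        bad = set(np.unique(self.labels)) - {POSITIVE, NEGATIVE, UNLABELED}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    def subset(self, mask: np.ndarray) -> "EmbeddingDataset":
        return EmbeddingDataset(
            ids=self.ids[mask],
            features=self.features[mask],
            labels=self.labels[mask],
            true_cluster=self.true_cluster[mask],
            noisy=self.noisy[mask],
            split=self.split[mask],
        )

    def by_split(self, split: str) -> "EmbeddingDataset":
        return self.subset(self.split == split)

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {i: k for k, i in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown id {exc.args[0]!r}") from None

    def to_frame(self) -> pd.DataFrame:
        d = self.features.shape[1]
        frame = pd.DataFrame(
            {
                "id": self.ids,
                "label": self.labels,
                "split": self.split,
                "noisy": self.noisy,
                "true_cluster": self.true_cluster,
            }
        )
        feats = pd.DataFrame(
            self.features, columns=[f"f_{j}" for j in range(d)]
        )
        return pd.concat([frame, feats.set_index(frame.index)], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EmbeddingDataset":
        feat_cols = [c for c in frame.columns if c.startswith("f_")]
        feat_cols.sort(key=lambda c: int(c.split("_", 1)[1]))
        true_cluster = (
            frame["true_cluster"].to_numpy(dtype=int)
            if "true_cluster" in frame
            else np.full(len(frame), BACKGROUND)
        )
        return cls(
            ids=frame["id"].astype(str).to_numpy(),
            features=frame[feat_cols].to_numpy(dtype=float),
            labels=frame.get("label", pd.Series([UNLABELED] * len(frame)))
            .astype(str)
            .to_numpy(),
            true_cluster=true_cluster,
            noisy=frame.get("noisy", pd.Series([False] * len(frame)))
            .astype(bool)
            .to_numpy(),
            split=frame.get("split", pd.Series(["train_labeled"] * len(frame)))
            .astype(str)
            .to_numpy(),
        )

    @classmethod
    def from_csv(cls, path) -> "EmbeddingDataset":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class OracleLabeler:
    """Simulated human expert with a per-loop query budget.

    The expert's limited annotation time is modeled as a maximum number of
    label queries per human-in-the-loop iteration; ``reset_loop`` starts a
    fresh budget at the top of each loop.
    """

    truth: Mapping[str, str]
    budget: int
    queries_used: int = 0

    def __post_init__(self) -> None:
        if self.budget < 0:
            raise ValueError("budget must be nonnegative")

    def reset_loop(self) -> None:
        self.queries_used = 0

    @property
    def remaining(self) -> int:
        return self.budget - self.queries_used

    def query(self, cell_id: str) -> str:
        if self.queries_used >= self.budget:
            raise BudgetExhaustedError(
                f"labeling budget of {self.budget} queries exhausted this loop"
            )
        if cell_id not in self.truth:
            raise KeyError(f"unknown id {cell_id!r}")
        self.queries_used += 1
        return self.truth[cell_id]


def make_oracle(dataset: EmbeddingDataset, budget_per_loop: int) -> OracleLabeler:
    """Wrap a ground-truth-labeled dataset as a budgeted labeling oracle."""
    if np.any(dataset.labels == UNLABELED):
        raise ValueError("dataset must carry ground-truth labels for all ids")
    truth = dict(zip(dataset.ids.tolist(), dataset.labels.tolist()))
    return OracleLabeler(truth=truth, budget=budget_per_loop)


def _cluster_centers(n_clusters: int, dim: int, rng: np.random.Generator,
                     min_distance: float) -> np.ndarray:
    # Vertices of a scaled simplex: pairwise distance sqrt(2) * scale.
    # min_distance is in units of the (unit) within-cluster SD, so density
    # clustering can recover the blobs.
    if n_clusters > dim:
        raise ValueError("n_clusters may not exceed dim for simplex placement")
    scale = min_distance / np.sqrt(2.0)
    centers = np.zeros((n_clusters, dim))
    axes = rng.permutation(dim)[:n_clusters]
    centers[np.arange(n_clusters), axes] = scale
    return centers


def generate_latent_dataset(
    config: SyntheticLatentConfig, seed: int | None = None
) -> EmbeddingDataset:
    """Draw a clustered-Gaussian embedding dataset with ground truth.

    Each cluster contributes ``points_per_cluster[i]`` points; a fraction
    ``class_mix[i]`` of them are positives whose mean is offset from the
    negatives' mean by ``separability[i]`` within-class SDs.  A further
    ``background_fraction`` of the total is drawn uniformly over the
    bounding box of the clustered points (true cluster = background), and
    ``noisy_fraction`` of all points are replaced by heavy-tailed
    (Cauchy-like) outliers flagged ``noisy``.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    # keep 8 SD of clearance between cluster blobs *beyond* the class-mean
    # offset, so clusters stay distinct however separable their classes are
    min_distance = 8.0 + max(config.separability)
    centers = _cluster_centers(config.n_clusters, config.dim, rng, min_distance)

    # one random class-offset axis shared by all clusters: the positive /
    # negative contrast is a dataset-level property of the representation
    direction = rng.standard_normal(config.dim)
    direction /= np.linalg.norm(direction)

    feats, labels, clusters = [], [], []
    for i in range(config.n_clusters):
        n_i = config.points_per_cluster[i]
        n_pos = int(round(config.class_mix[i] * n_i))
        offset = 0.5 * config.separability[i] * direction
        pos = centers[i] + offset + rng.standard_normal((n_pos, config.dim))
        neg = centers[i] - offset + rng.standard_normal((n_i - n_pos, config.dim))
        feats.append(np.vstack([pos, neg]))
        labels.extend([POSITIVE] * n_pos + [NEGATIVE] * (n_i - n_pos))
        clusters.extend([i] * n_i)

    features = np.vstack(feats)
    n_clustered = len(features)
    n_background = int(round(config.background_fraction * n_clustered))
    if n_background:
        lo = features.min(axis=0)
        hi = features.max(axis=0)
        bg = rng.uniform(lo, hi, size=(n_background, config.dim))
        features = np.vstack([features, bg])
        labels.extend(
            rng.choice([POSITIVE, NEGATIVE], size=n_background).tolist()
        )
        clusters.extend([BACKGROUND] * n_background)

    n_total = len(features)
    noisy = np.zeros(n_total, dtype=bool)
    n_noisy = int(round(config.noisy_fraction * n_total))
    if n_noisy:
        idx = rng.choice(n_total, size=n_noisy, replace=False)
        scale = max(features.std(), 1.0)
        # df=1 Student t == Cauchy: heavy tails give the noise filter
        # something learnable
        features[idx] = scale * rng.standard_t(df=1, size=(n_noisy, config.dim))
        noisy[idx] = True

    return EmbeddingDataset(
        ids=np.array([f"cell_{k:06d}" for k in range(n_total)]),
        features=features,
        labels=np.array(labels),
        true_cluster=np.array(clusters, dtype=int),
        noisy=noisy,
        split=np.array(["train_labeled"] * n_total),
    )


def assign_splits(
    dataset: EmbeddingDataset,
    fractions: Mapping[str, float],
    seed: int,
) -> EmbeddingDataset:
    """Randomly tag every row with a split drawn from ``fractions``.

    Fractions must sum to 1 (tolerance 1e-9).  Assignment is a seeded
    permutation, so each split's size is exact up to rounding.
    """
    bad = set(fractions) - set(SPLITS)
    if bad:
        raise ValueError(f"unknown split tags: {sorted(bad)}")
    total = float(sum(fractions.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {total}")
    n = len(dataset)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    split = np.empty(n, dtype=object)
    start = 0
    items = list(fractions.items())
    for k, (tag, frac) in enumerate(items):
        stop = n if k == len(items) - 1 else start + int(round(frac * n))
        split[order[start:stop]] = tag
        start = stop
    out = dataset.subset(np.ones(n, dtype=bool))
    out.split = split.astype(str)
    return out


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap."""


def generate_cartridge(
    image_height: int = CARTRIDGE_SHAPE[0],
    image_width: int = CARTRIDGE_SHAPE[1],
    n_cells: int = 50,
    seed: int = 0,
    ctc_fraction: float = 0.3,
    cell_sigma: float = 4.0,
    max_tries: int = 200,
):
    """Render a synthetic three-channel cartridge tile plus instance mask.

    Every cell is a Gaussian intensity blob, bright in DAPI; a
    ``ctc_fraction`` subset is additionally bright in CK (tumor-cell-like)
    and the disjoint remainder bright in CD45 (leukocyte-like).  Returns
    ``(channels, mask, truth)`` where ``channels`` is a dict with keys
    ``dapi``/``ck``/``cd45`` (uint16 arrays), ``mask`` is an int32 instance
    mask (0 = background) and ``truth`` is a DataFrame with columns
    ``instance, row, col, cell_class``.
    """
    if image_height <= 0 or image_width <= 0:
        raise ValueError("image dimensions must be positive")
    if n_cells < 0:
        raise ValueError("n_cells must be nonnegative")
    rng = np.random.default_rng(seed)
    shape = (image_height, image_width)
    dapi = np.zeros(shape, dtype=np.float64)
    ck = np.zeros(shape, dtype=np.float64)
    cd45 = np.zeros(shape, dtype=np.float64)
    mask = np.zeros(shape, dtype=np.int32)

    radius = int(np.ceil(2 * cell_sigma))
    margin = radius + 1
    min_sep = 2.5 * radius
    centers: list[tuple[int, int]] = []
    for _ in range(n_cells):
        for _try in range(max_tries):
            r = int(rng.integers(margin, image_height - margin))
            c = int(rng.integers(margin, image_width - margin))
            if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep**2
                   for r0, c0 in centers):
                centers.append((r, c))
                break
        else:
            raise PlacementError(
                f"could not place cell {len(centers) + 1} of {n_cells} "
                f"without overlap after {max_tries} tries"
            )

    n_ctc = int(round(ctc_fraction * n_cells))
    classes = np.array(["ctc"] * n_ctc + ["leukocyte"] * (n_cells - n_ctc))
    rng.shuffle(classes)

    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    blob = np.exp(-(yy**2 + xx**2) / (2 * cell_sigma**2))
    disk = (yy**2 + xx**2) <= radius**2

    rows = []
    for k, ((r, c), cls) in enumerate(zip(centers, classes), start=1):
        sl = (slice(r - radius, r + radius + 1), slice(c - radius, c + radius + 1))
        amp = rng.uniform(0.6, 1.0)
        dapi[sl] += amp * blob
        if cls == "ctc":
            ck[sl] += rng.uniform(0.6, 1.0) * blob
        else:
            cd45[sl] += rng.uniform(0.6, 1.0) * blob
        mask[sl][disk] = k
        rows.append({"instance": k, "row": r, "col": c, "cell_class": cls})

    channels = {"dapi": dapi, "ck": ck, "cd45": cd45}
    channels = {
        k: (np.clip(v, 0, 1) * 65535).astype(np.uint16)
        for k, v in channels.items()
    }
    truth = pd.DataFrame(rows, columns=["instance", "row", "col", "cell_class"])
    return channels, mask, truth
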