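"""Binary cell classification, noise pre-filtering, and candidate dedup.

The classifier contract is a margin-based model with calibrated
probability output for the positive (CTC) class.  The concrete model is a
support vector machine with an RBF kernel at library defaults, probability
calibration enabled, deterministic tie-breaking, and optional balanced
class weighting — CTCs are rare, so the negative class otherwise swamps
the margin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .synthdata import NEGATIVE, POSITIVE


@dataclass(frozen=True)
class Prediction:
    id: str
    prob_positive: float
    label: str


class ClassifierModel:
    """Margin classifier with probabilistic output over reduced features."""

    def __init__(self, weighting: str = "balanced", seed: int = 0):
        if weighting not in ("balanced", "none"):
            raise ValueError("weighting must be 'balanced' or 'none'")
        self.weighting = weighting
        self.seed = seed
        self._svc: SVC | None = None

    @property
    def fitted(self) -> bool:
        return self._svc is not None

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "ClassifierModel":
        features = np.asarray(features, dtype=float)
        labels = np.asarray(labels)
        if features.shape[0] < 2:
            raise ValueError("need at least 2 training points")
        present = set(labels.tolist())
        for cls in (POSITIVE, NEGATIVE):
            if cls not in present:
                raise ValueError(f"training data lacks the {cls} class")
        y = (labels == POSITIVE).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            self._svc = SVC(
                class_weight="balanced" if self.weighting == "balanced" else None,
                probability=True,
                break_ties=True,
                cache_size=1000,
                random_state=self.seed,
            )
            self._svc.fit(features, y)
        return self

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("classifier has not been fitted")
        features = np.asarray(features, dtype=float)
        pos_col = list(self._svc.classes_).index(1)
        return self._svc.predict_proba(features)[:, pos_col]


def fit_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    weighting: str = "balanced",
    seed: int = 0,
) -> ClassifierModel:
    """Fit the binary CTC / non-CTC classifier; both classes must be present."""
    return ClassifierModel(weighting=weighting, seed=seed).fit(features, labels)


def predict(
    model: ClassifierModel,
    features: np.ndarray,
    ids: Sequence[str] | None = None,
    threshold: float = 0.5,
) -> list[Prediction]:
    """Score features and derive labels by ``prob > threshold``.

    Output order matches input order.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    probs = model.predict_proba(features)
    if ids is None:
        ids = [str(k) for k in range(len(probs))]
    return [
        Prediction(
            id=str(i),
            prob_positive=float(p),
            label=POSITIVE if p > threshold else NEGATIVE,
        )
        for i, p in zip(ids, probs)
    ]


class NoiseFilter:
    """Pre-filter flagging uninterpretable (noisy / artifact) cell images.

    Trained on expert-curated noisy vs clean examples; applied to a pool it
    returns the retained clean subset.
    """

    def __init__(self, seed: int = 0):
        self.seed = seed
        self._svc: SVC | None = None

    def fit(self, noisy_features: np.ndarray, clean_features: np.ndarray):
        noisy_features = np.asarray(noisy_features, dtype=float)
        clean_features = np.asarray(clean_features, dtype=float)
        if len(noisy_features) == 0:
            raise ValueError("noisy example set is empty")
        if len(clean_features) == 0:
            raise ValueError("clean example set is empty")
        x = np.vstack([noisy_features, clean_features])
        y = np.concatenate(
            [np.ones(len(noisy_features), dtype=int),
             np.zeros(len(clean_features), dtype=int)]
        )
        self._svc = SVC(class_weight="balanced", random_state=self.seed)
        self._svc.fit(x, y)
        return self

    def is_noisy(self, features: np.ndarray) -> np.ndarray:
        if self._svc is None:
            raise RuntimeError("noise filter has not been fitted")
        return self._svc.predict(np.asarray(features, dtype=float)).astype(bool)

    def retain(self, features: np.ndarray) -> np.ndarray:
        """Boolean mask of the clean (retained) subset."""
        return ~self.is_noisy(features)


def fit_noise_filter(
    noisy_features: np.ndarray, clean_features: np.ndarray, seed: int = 0
) -> NoiseFilter:
    return NoiseFilter(seed=seed).fit(noisy_features, clean_features)


def remove_duplicates(
    candidates: Sequence[Prediction],
    centroids: Sequence[tuple[float, float]],
    radius: float,
) -> list[Prediction]:
    """Collapse candidates whose centroids lie within ``radius`` of each other.

    Proximity is closed transitively (connected components of the
    within-radius graph); within each component the candidate with the
    highest positive probability survives, ties broken by lowest id.
    """
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    if len(candidates) != len(centroids):
        raise ValueError("candidates and centroids must have equal length")
    n = len(candidates)
    if n == 0:
        return []
    pts = np.asarray(centroids, dtype=float)

    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    for a, b in tree.query_pairs(radius):
        union(a, b)

    best: dict[int, int] = {}
    for k in range(n):
        root = find(k)
        if root not in best:
            best[root] = k
        else:
            cur = best[root]
            if (
                candidates[k].prob_positive > candidates[cur].prob_positive
                or (
                    candidates[k].prob_positive == candidates[cur].prob_positive
                    and candidates[k].id < candidates[cur].id
                )
            ):
                best[root] = k
    keep = sorted(best.values())
    return [candidates[k] for k in keep]
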