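"""Cluster-based human-in-the-loop (HiL) sampling engines.

The central idea: evaluate the classifier's F1 score separately for each
latent-space stratum (density cluster or background), convert those scores
into sampling weights inversely proportional to performance,

    c_i = (1 - s_i) / sum_j (1 - s_j),

and spend the limited labeling budget preferentially on the strata where
the classifier is weakest.  Three experiment engines implement this
against a random-sampling baseline arm:

* scenario 1 (*limited global data*) — tiny initial training pool, 100 new
  labeled samples per loop, strata weighted by Monte-Carlo-validated F1;
* scenario 2 (*limited local data*) — one cluster's training data is
  artificially scarce and is refilled 20% per loop;
* real-world — new labels come from a budgeted oracle standing in for a
  human expert reviewing predicted-negative candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .classify import ClassifierModel, fit_classifier
from .synthdata import BACKGROUND, NEGATIVE, POSITIVE, EmbeddingDataset, OracleLabeler

logger = logging.getLogger(__name__)

TOTAL = "total"

CLUSTER_SPECIFIC = "cluster_specific"
RANDOM = "random"


@dataclass(frozen=True)
class StratumMetrics:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            return 1.0 if self.fn == 0 else 0.0
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            return 1.0 if self.fp == 0 else 0.0
        return self.tp / (self.tp + self.fn)

    @property
    def f1(self) -> float:
        # Degenerate conventions: a stratum with no positives anywhere
        # (TP = FP = FN = 0) is solved, F1 = 1, so it attracts no samples;
        # any errors without a single true positive give F1 = 0.
        if self.tp == 0:
            return 1.0 if self.fp == 0 and self.fn == 0 else 0.0
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r)


@dataclass
class ClusterMetrics:
    """Per-stratum confusion counts and F1, plus a 'total' entry."""

    by_stratum: dict[object, StratumMetrics]

    def f1_map(self, include_total: bool = False) -> dict[object, float]:
        return {
            k: v.f1
            for k, v in self.by_stratum.items()
            if include_total or k != TOTAL
        }

    @property
    def overall_f1(self) -> float:
        return self.by_stratum[TOTAL].f1


def per_cluster_f1(
    predictions: Mapping[str, str] | Sequence[str],
    labels: Mapping[str, str] | Sequence[str],
    stratum_map: Mapping[str, int],
    ids: Sequence[str] | None = None,
) -> ClusterMetrics:
    """Confusion counts and F1 per stratum and for the whole set.

    ``predictions`` and ``labels`` are either id-keyed mappings or
    sequences aligned with ``ids``.  Every evaluated id must appear in
    ``stratum_map``.
    """
    if ids is None:
        if not isinstance(predictions, Mapping) or not isinstance(labels, Mapping):
            raise ValueError("ids required when predictions/labels are sequences")
        ids = list(predictions.keys())
    pred = (
        [predictions[i] for i in ids]
        if isinstance(predictions, Mapping)
        else list(predictions)
    )
    true = (
        [labels[i] for i in ids] if isinstance(labels, Mapping) else list(labels)
    )
    missing = [i for i in ids if i not in stratum_map]
    if missing:
        raise ValueError(f"ids missing from stratum map: {missing[:10]}")

    counts: dict[object, list[int]] = {TOTAL: [0, 0, 0]}
    for stratum in set(stratum_map[i] for i in ids):
        counts[stratum] = [0, 0, 0]
    for i, p, t in zip(ids, pred, true):
        for key in (stratum_map[i], TOTAL):
            c = counts[key]
            if p == POSITIVE and t == POSITIVE:
                c[0] += 1
            elif p == POSITIVE and t == NEGATIVE:
                c[1] += 1
            elif p == NEGATIVE and t == POSITIVE:
                c[2] += 1
    return ClusterMetrics(
        by_stratum={
            k: StratumMetrics(tp=v[0], fp=v[1], fn=v[2])
            for k, v in counts.items()
        }
    )


def sampling_weights(f1_by_stratum: Mapping[object, float]) -> dict[object, float]:
    """Inverse-F1 sampling frequencies c_i = (1 - s_i) / sum_j (1 - s_j).

    A stratum with perfect F1 gets weight 0; if every stratum is perfect
    the weights fall back to uniform.
    """
    if not f1_by_stratum:
        raise ValueError("f1_by_stratum is empty")
    for k, s in f1_by_stratum.items():
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"F1 score for stratum {k!r} outside [0, 1]: {s}")
    keys = list(f1_by_stratum)
    deficits = np.array([1.0 - f1_by_stratum[k] for k in keys])
    total = deficits.sum()
    if total <= 0:
        weights = np.full(len(keys), 1.0 / len(keys))
    else:
        weights = deficits / total
    return dict(zip(keys, weights.tolist()))


def allocate_draws(
    weights: Mapping[object, float],
    budget: int,
    pool_sizes: Mapping[object, int],
    rng: np.random.Generator,
) -> dict[object, int]:
    """Split a labeling budget over strata by a multinomial draw.

    Draws land in stratum i with probability c_i; a stratum whose pool is
    exhausted forfeits its excess, which is re-allocated among strata with
    remaining pool using renormalized weights.  The returned counts sum to
    ``min(budget, total pool)``.
    """
    if budget < 0:
        raise ValueError("budget must be nonnegative")
    keys = list(weights)
    if any(pool_sizes.get(k, 0) < 0 for k in keys):
        raise ValueError("pool sizes must be nonnegative")
    counts = {k: 0 for k in keys}
    capacity = {k: int(pool_sizes.get(k, 0)) for k in keys}
    remaining = min(budget, sum(capacity.values()))
    probs = np.array([max(weights[k], 0.0) for k in keys], dtype=float)
    while remaining > 0:
        open_idx = [j for j, k in enumerate(keys) if capacity[k] > counts[k]]
        p = probs[open_idx]
        if p.sum() <= 0:
            p = np.ones(len(open_idx))
        p = p / p.sum()
        draw = rng.multinomial(remaining, p)
        for j, d in zip(open_idx, draw):
            k = keys[j]
            take = min(d, capacity[k] - counts[k])
            counts[k] += int(take)
        remaining = min(budget, sum(capacity.values())) - sum(counts.values())
    return counts


def mc_validation_f1(
    features: np.ndarray,
    labels: np.ndarray,
    strata: np.ndarray,
    rng: np.random.Generator,
    folds: int = 100,
    train_frac: float = 0.9,
    combine: str = "pooled",
    weighting: str = "balanced",
    return_info: bool = False,
):
    """Per-stratum F1 from Monte-Carlo cross-validation of a labeled pool.

    Each fold is a fresh *unstratified* random train/validation split
    (default 90/10).  With ``combine='pooled'`` validation predictions are
    accumulated across folds into pooled confusion counts per stratum and
    F1 is computed once on the pooled counts; ``combine='mean'`` averages
    per-fold F1 scores instead.  A fold whose training half is
    single-class predicts that class for every validation point.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    strata = np.asarray(strata)
    n = len(features)
    if n < 10:
        raise ValueError("pool must contain at least 10 points")
    present = set(labels.tolist())
    if POSITIVE not in present or NEGATIVE not in present:
        raise ValueError("pool must contain both classes")
    if combine not in ("pooled", "mean"):
        raise ValueError("combine must be 'pooled' or 'mean'")
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 1)

    ids = np.array([str(k) for k in range(n)])
    stratum_map = dict(zip(ids.tolist(), strata.tolist()))
    pooled: dict[object, list[int]] = {}
    fold_f1s: list[dict[object, float]] = []
    n_predictions = 0
    svc_seed = int(rng.integers(0, 2**31 - 1))
    for _ in range(folds):
        perm = rng.permutation(n)
        train_idx, val_idx = perm[:n_train], perm[n_train:]
        train_labels = labels[train_idx]
        if len(set(train_labels.tolist())) < 2:
            only = train_labels[0]
            preds = [only] * len(val_idx)
        else:
            model = fit_classifier(
                features[train_idx], train_labels, weighting=weighting,
                seed=svc_seed,
            )
            probs = model.predict_proba(features[val_idx])
            preds = [POSITIVE if p > 0.5 else NEGATIVE for p in probs]
        n_predictions += len(val_idx)
        metrics = per_cluster_f1(
            preds, labels[val_idx].tolist(), stratum_map,
            ids=ids[val_idx].tolist(),
        )
        if combine == "mean":
            fold_f1s.append(metrics.f1_map())
        else:
            for k, m in metrics.by_stratum.items():
                if k == TOTAL:
                    continue
                c = pooled.setdefault(k, [0, 0, 0])
                c[0] += m.tp
                c[1] += m.fp
                c[2] += m.fn

    all_strata = set(strata.tolist())
    if combine == "mean":
        out = {}
        for k in all_strata:
            vals = [f[k] for f in fold_f1s if k in f]
            out[k] = float(np.mean(vals)) if vals else 1.0
    else:
        out = {
            k: StratumMetrics(*pooled.get(k, [0, 0, 0])).f1 for k in all_strata
        }
    if return_info:
        info = {
            "folds": folds,
            "n_validation_per_fold": n - n_train,
            "n_pooled_predictions": n_predictions,
        }
        return out, info
    return out


@dataclass(frozen=True)
class ExperimentConfig:
    """Knobs of the three HiL experiments (defaults follow the study design)."""

    n_loops: int = 4
    n_repeats: int = 5
    initial_pool_size: int = 100
    per_loop_budget: int = 100
    init_fraction: float = 0.2
    other_fraction: float = 0.8
    loop_increment: float = 0.2
    relabel_pool_size: int = 1000
    oracle_budget: int = 11
    threshold: float = 0.5
    mc_folds: int = 100
    mc_train_frac: float = 0.9
    mc_combine: str = "pooled"
    include_background_in_sampling: bool = True
    weighting: str = "balanced"

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class LoopRecord:
    loop: int
    pool_ids: tuple[str, ...]
    added_ids: tuple[str, ...]
    f1_by_stratum: dict[object, float]
    overall_f1: float


@dataclass
class RunResult:
    """Per-loop trajectory of one seeded HiL run (loop 0 = initialization)."""

    arm: str
    seed: int
    loops: list[LoopRecord] = field(default_factory=list)

    def f1_trajectory(self, stratum: object = TOTAL) -> list[float]:
        if stratum == TOTAL:
            return [r.overall_f1 for r in self.loops]
        return [r.f1_by_stratum[stratum] for r in self.loops]

    def final_f1(self, stratum: object = TOTAL) -> float:
        return self.f1_trajectory(stratum)[-1]

    def validate_nesting(self) -> None:
        prev: set[str] = set()
        seen_added: set[str] = set()
        for rec in self.loops:
            pool = set(rec.pool_ids)
            if not prev <= pool:
                raise AssertionError("training pools are not nested")
            if set(rec.added_ids) & seen_added:
                raise AssertionError("added ids duplicated across loops")
            seen_added |= set(rec.added_ids)
            prev = pool


def _evaluate(
    model: ClassifierModel,
    test: EmbeddingDataset,
    stratum_map: Mapping[str, int],
    threshold: float,
) -> ClusterMetrics:
    probs = model.predict_proba(test.features)
    preds = [POSITIVE if p > threshold else NEGATIVE for p in probs]
    return per_cluster_f1(
        preds, test.labels.tolist(), stratum_map, ids=test.ids.tolist()
    )


def _record(
    data: EmbeddingDataset,
    pool_ids: list[str],
    added: list[str],
    test: EmbeddingDataset,
    stratum_map: Mapping[str, int],
    config: ExperimentConfig,
    loop: int,
    seed: int,
    labels_override: Mapping[str, str] | None = None,
) -> LoopRecord:
    idx = data.index_of(pool_ids)
    labels = data.labels[idx]
    if labels_override:
        labels = np.array(
            [labels_override.get(i, l) for i, l in zip(pool_ids, labels)]
        )
    model = fit_classifier(
        data.features[idx], labels, weighting=config.weighting, seed=seed
    )
    metrics = _evaluate(model, test, stratum_map, config.threshold)
    return LoopRecord(
        loop=loop,
        pool_ids=tuple(pool_ids),
        added_ids=tuple(added),
        f1_by_stratum=metrics.f1_map(),
        overall_f1=metrics.overall_f1,
    )


def _sampling_f1(
    data: EmbeddingDataset,
    pool_ids: list[str],
    stratum_map: Mapping[str, int],
    config: ExperimentConfig,
    rng: np.random.Generator,
) -> dict[object, float]:
    idx = data.index_of(pool_ids)
    strata = np.array([stratum_map[i] for i in pool_ids])
    return mc_validation_f1(
        data.features[idx],
        data.labels[idx],
        strata,
        rng,
        folds=config.mc_folds,
        train_frac=config.mc_train_frac,
        combine=config.mc_combine,
        weighting=config.weighting,
    )


def run_scenario1(
    data: EmbeddingDataset,
    stratum_map: Mapping[str, int],
    config: ExperimentConfig,
    seed: int,
    test: EmbeddingDataset | None = None,
) -> tuple[RunResult, RunResult]:
    """Limited-global-data experiment: (cluster_specific, random) arms.

    The labeled training set is split into a small random initial pool and
    a relabeling pool.  Each loop the classifier is fitted and evaluated on
    the test set; the cluster-specific arm then estimates per-stratum F1 by
    Monte-Carlo cross-validation of the current pool and draws the next
    budget of samples with inverse-F1 frequencies, while the random arm
    draws uniformly from the whole relabeling pool.  Both arms share the
    same initial pool.
    """
    if test is None:
        test = data.by_split("test")
    train = data.by_split("train_labeled")
    missing = [i for i in train.ids.tolist() + test.ids.tolist()
               if i not in stratum_map]
    if missing:
        raise ValueError(f"ids missing from stratum map: {missing[:10]}")

    rng = np.random.default_rng(seed)
    train_ids = train.ids.tolist()
    if len(train_ids) <= config.initial_pool_size:
        raise ValueError("labeled training set smaller than the initial pool")
    initial = rng.choice(
        train_ids, size=config.initial_pool_size, replace=False
    ).tolist()
    relabel_all = sorted(set(train_ids) - set(initial))

    results = []
    for arm in (CLUSTER_SPECIFIC, RANDOM):
        arm_rng = np.random.default_rng([seed, 1 if arm == RANDOM else 0])
        pool = list(initial)
        relabel = list(relabel_all)
        added: list[str] = []
        result = RunResult(arm=arm, seed=seed)
        for loop in range(config.n_loops + 1):
            result.loops.append(
                _record(data, pool, added, test, stratum_map, config, loop, seed)
            )
            if loop == config.n_loops:
                break
            if not relabel:
                logger.warning("relabeling pool exhausted at loop %d", loop)
                break
            if arm == CLUSTER_SPECIFIC:
                f1s = _sampling_f1(data, pool, stratum_map, config, arm_rng)
                if not config.include_background_in_sampling:
                    f1s = {k: v for k, v in f1s.items() if k != BACKGROUND}
                weights = sampling_weights(f1s)
                by_stratum: dict[object, list[str]] = {}
                for i in relabel:
                    by_stratum.setdefault(stratum_map[i], []).append(i)
                pools = {k: len(v) for k, v in by_stratum.items()}
                weights = {k: weights.get(k, 0.0) for k in pools}
                counts = allocate_draws(
                    weights, config.per_loop_budget, pools, arm_rng
                )
                added = []
                for k, cnt in counts.items():
                    if cnt:
                        added.extend(
                            arm_rng.choice(
                                by_stratum[k], size=cnt, replace=False
                            ).tolist()
                        )
            else:
                cnt = min(config.per_loop_budget, len(relabel))
                added = arm_rng.choice(relabel, size=cnt, replace=False).tolist()
            pool = pool + added
            relabel = sorted(set(relabel) - set(added))
        results.append(result)
    return results[0], results[1]


def run_scenario2(
    data: EmbeddingDataset,
    stratum_map: Mapping[str, int],
    main_cluster: int,
    config: ExperimentConfig,
    seed: int,
    test: EmbeddingDataset | None = None,
) -> tuple[RunResult, RunResult]:
    """Limited-local-data experiment: one cluster's training data is scarce.

    The main cluster's labeled training data is pruned to 20% of its size,
    all other strata to 80%.  The cluster-specific arm restores the main
    cluster 20% per loop (a fixed random order) until all of it is used;
    the random arm draws the same per-loop counts from a pool made of 20%
    of every stratum's left-out samples, including the main cluster's.
    """
    if test is None:
        test = data.by_split("test")
    train = data.by_split("train_labeled")
    rng = np.random.default_rng(seed)

    by_stratum: dict[object, list[str]] = {}
    for i in train.ids.tolist():
        by_stratum.setdefault(stratum_map[i], []).append(i)
    if main_cluster not in by_stratum:
        raise ValueError(f"main cluster {main_cluster} has no labeled points")
    main_ids = by_stratum[main_cluster]
    if len(main_ids) < 5:
        raise ValueError(
            f"main cluster {main_cluster} has fewer than 5 labeled points"
        )

    initial: list[str] = []
    leftover_random_pool: list[str] = []
    main_order: list[str] = []
    for stratum, ids in sorted(by_stratum.items(), key=lambda kv: str(kv[0])):
        ids = list(ids)
        rng.shuffle(ids)
        if stratum == main_cluster:
            n_init = int(round(config.init_fraction * len(ids)))
            n_init = max(n_init, 1)
            initial.extend(ids[:n_init])
            main_order = ids[n_init:]  # fixed order of future 20% chunks
            left_out = ids[n_init:]
        else:
            n_init = int(round(config.other_fraction * len(ids)))
            initial.extend(ids[:n_init])
            left_out = ids[n_init:]
        # the random arm's reservoir: a slice of every stratum's left-out
        # samples amounting to 20% of the stratum's original labeled size
        # (for non-main strata that is their entire left-out 20%)
        n_pool = min(int(round(0.2 * len(ids))), len(left_out))
        leftover_random_pool.extend(left_out[:n_pool])

    # per-loop chunk sizes: remaining main-cluster samples split over loops,
    # each ~ loop_increment of the cluster's full size
    n_main = len(main_ids)
    per_loop = int(round(config.loop_increment * n_main))
    chunks: list[list[str]] = []
    start = 0
    for loop in range(config.n_loops):
        stop = len(main_order) if loop == config.n_loops - 1 else min(
            start + per_loop, len(main_order)
        )
        chunks.append(main_order[start:stop])
        start = stop

    results = []
    for arm in (CLUSTER_SPECIFIC, RANDOM):
        arm_rng = np.random.default_rng([seed, 1 if arm == RANDOM else 0])
        pool = list(initial)
        random_pool = list(leftover_random_pool)
        result = RunResult(arm=arm, seed=seed)
        result.loops.append(
            _record(data, pool, [], test, stratum_map, config, 0, seed)
        )
        for loop in range(1, config.n_loops + 1):
            chunk = chunks[loop - 1]
            if arm == CLUSTER_SPECIFIC:
                added = list(chunk)
            else:
                available = [i for i in random_pool if i not in pool]
                cnt = min(len(chunk), len(available))
                if cnt < len(chunk):
                    logger.warning(
                        "random-arm pool exhausted at loop %d", loop
                    )
                added = (
                    arm_rng.choice(available, size=cnt, replace=False).tolist()
                    if cnt
                    else []
                )
            pool = pool + added
            result.loops.append(
                _record(data, pool, added, test, stratum_map, config, loop, seed)
            )
        results.append(result)
    return results[0], results[1]


def run_realworld(
    data: EmbeddingDataset,
    stratum_map: Mapping[str, int],
    oracle: OracleLabeler,
    target_cluster: int,
    config: ExperimentConfig,
    seed: int,
    test: EmbeddingDataset | None = None,
    noise_filter=None,
) -> tuple[RunResult, RunResult]:
    """Budgeted-oracle experiment on initially unlabeled data.

    The initial pool is the whole labeled training set.  Each loop the
    cluster-specific arm asks the oracle (within its per-loop budget) about
    predicted-negative samples of the target cluster drawn from an
    unlabeled relabeling pool; confirmed positives join the training pool
    as new CTC examples.  The random arm queries predicted negatives of any
    stratum until it has matched the cluster-specific arm's per-loop yield.
    """
    if test is None:
        test = data.by_split("test")
    train = data.by_split("train_labeled")
    unlabeled = data.by_split("train_unlabeled")
    rng = np.random.default_rng(seed)

    pool_mask = np.ones(len(unlabeled), dtype=bool)
    if noise_filter is not None:
        pool_mask = noise_filter.retain(unlabeled.features)
    clean = unlabeled.subset(pool_mask)
    n_pool = min(config.relabel_pool_size, len(clean))
    chosen = rng.choice(len(clean), size=n_pool, replace=False)
    relabel = clean.subset(np.isin(np.arange(len(clean)), chosen))

    missing = [i for i in relabel.ids.tolist() if i not in stratum_map]
    if missing:
        raise ValueError(f"ids missing from stratum map: {missing[:10]}")

    per_loop_yield: list[int] = []
    results = []
    for arm in (CLUSTER_SPECIFIC, RANDOM):
        arm_rng = np.random.default_rng([seed, 1 if arm == RANDOM else 0])
        pool = train.ids.tolist()
        overrides: dict[str, str] = {}
        remaining = set(relabel.ids.tolist())
        result = RunResult(arm=arm, seed=seed)
        result.loops.append(
            _record(data, pool, [], test, stratum_map, config, 0, seed)
        )
        for loop in range(1, config.n_loops + 1):
            idx = data.index_of(pool)
            labels = np.array(
                [overrides.get(i, l) for i, l in zip(pool, data.labels[idx])]
            )
            model = fit_classifier(
                data.features[idx], labels, weighting=config.weighting,
                seed=seed,
            )
            rel_ids = [i for i in relabel.ids.tolist() if i in remaining]
            if not rel_ids:
                logger.warning("relabeling pool empty at loop %d", loop)
                result.loops.append(
                    _record(data, pool, [], test, stratum_map, config, loop,
                            seed, overrides)
                )
                continue
            rel_idx = relabel.index_of(rel_ids)
            probs = model.predict_proba(relabel.features[rel_idx])
            predicted_negative = [
                i for i, p in zip(rel_ids, probs) if p <= config.threshold
            ]
            if arm == CLUSTER_SPECIFIC:
                candidates = [
                    i for i in predicted_negative
                    if stratum_map[i] == target_cluster
                ]
                arm_rng.shuffle(candidates)
                oracle.reset_loop()
                added = []
                for i in candidates:
                    if oracle.remaining <= 0:
                        break
                    if oracle.query(i) == POSITIVE:
                        added.append(i)
                per_loop_yield.append(len(added))
            else:
                target = per_loop_yield[loop - 1]
                candidates = list(predicted_negative)
                arm_rng.shuffle(candidates)
                added = []
                for i in candidates:
                    if len(added) >= target:
                        break
                    if oracle.truth[i] == POSITIVE:
                        added.append(i)
            for i in added:
                overrides[i] = POSITIVE
            remaining -= set(added)
            pool = pool + added
            result.loops.append(
                _record(data, pool, added, test, stratum_map, config, loop,
                        seed, overrides)
            )
        results.append(result)
    return results[0], results[1]
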