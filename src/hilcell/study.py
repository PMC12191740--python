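"""End-to-end study recipes on synthetic embeddings.

These functions wire the full pipeline — synthetic hard-cluster dataset,
PCA, joint UMAP + HDBSCAN clustering, and the paired human-in-the-loop
experiment arms — into single calls used by the command line, the test
suite, and the reproduction script.  The default conditions are the study
conditions: five 300-point embedding clusters of which one is hard
(class separability 0.5 within-class SDs vs 5.0 elsewhere), 100-sample
labeling loops, four loops per run.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from . import hil, latent
from .cli import hard_cluster_dataset
from .synthdata import EmbeddingDataset


@dataclass
class StudySetup:
    """Clustered study data shared by all paired experiment runs."""

    data: EmbeddingDataset          # features already PCA-reduced
    stratum_map: dict[str, int]
    hard_stratum: int
    n_clusters: int
    retained_variance: float


def prepare_study(
    n_clusters: int = 5,
    points_per_cluster: int = 300,
    dim: int = 128,
    n_components: int = 32,
    hard_cluster: int = 4,
    seed: int = 0,
) -> StudySetup:
    """Generate data, reduce, joint-cluster, and locate the hard stratum.

    The cluster analysis runs once on the joint unlabeled-train + test
    latent space and is shared across all seeded experiment repeats, as a
    real analysis would share a single clustering.  The hard stratum is
    the joint cluster holding the plurality of the designed hard cluster's
    points.
    """
    dataset = hard_cluster_dataset(
        n_clusters=n_clusters,
        points_per_cluster=points_per_cluster,
        dim=dim,
        hard_cluster=hard_cluster,
        seed=seed,
    )
    reducer = latent.fit_linear_reducer(dataset.features, n_components=n_components)
    reduced = latent.reduce_dataset(reducer, dataset)
    params = latent.PlanarEmbeddingParams(seed=seed)
    jc = latent.joint_cluster(
        reduced.by_split("train_unlabeled"),
        reduced.by_split("test"),
        reducer=_identity_reducer(reduced.dim),
        params=params,
    )
    stratum_map = dict(jc.stratum_map)
    rest = reduced.subset(~np.isin(reduced.ids, jc.ids))
    if len(rest):
        assigned = jc.assign(rest.features)
        stratum_map.update(dict(zip(rest.ids.tolist(), assigned.tolist())))

    hard_ids = reduced.ids[reduced.true_cluster == hard_cluster]
    votes = Counter(stratum_map[i] for i in hard_ids.tolist())
    hard_stratum = votes.most_common(1)[0][0]
    return StudySetup(
        data=reduced,
        stratum_map=stratum_map,
        hard_stratum=int(hard_stratum),
        n_clusters=jc.model.n_clusters,
        retained_variance=reducer.retained_variance,
    )


def _identity_reducer(dim: int) -> latent.LinearReducer:
    # features are already reduced; joint_cluster still wants a reducer
    return latent.LinearReducer(
        mean=np.zeros(dim),
        basis=np.eye(dim),
        explained_variance=np.ones(dim),
        total_variance=float(dim),
    )


@dataclass
class PairedOutcome:
    """Final-loop hard-cluster F1 of both arms for each seed."""

    seeds: list[int]
    cluster_specific: list[float]
    random: list[float]
    overall_cluster_specific: list[float]
    overall_random: list[float]

    @property
    def wins(self) -> int:
        return sum(
            c > r for c, r in zip(self.cluster_specific, self.random)
        )

    @property
    def ties(self) -> int:
        return sum(
            c == r for c, r in zip(self.cluster_specific, self.random)
        )

    def sign_test_p(self) -> float:
        """One-sided paired sign test: cluster-specific beats random."""
        n = len(self.seeds) - self.ties
        if n == 0:
            return 1.0
        return float(binomtest(self.wins, n, 0.5, alternative="greater").pvalue)


def run_paired_scenario1(
    setup: StudySetup,
    seeds: list[int],
    config: hil.ExperimentConfig | None = None,
) -> tuple[PairedOutcome, list[hil.RunResult]]:
    """Run scenario 1 for each seed; collect paired final hard-cluster F1."""
    if config is None:
        config = hil.ExperimentConfig()
    outcome = PairedOutcome(
        seeds=list(seeds), cluster_specific=[], random=[],
        overall_cluster_specific=[], overall_random=[],
    )
    results: list[hil.RunResult] = []
    for seed in seeds:
        cs, rnd = hil.run_scenario1(setup.data, setup.stratum_map, config, seed)
        outcome.cluster_specific.append(cs.final_f1(setup.hard_stratum))
        outcome.random.append(rnd.final_f1(setup.hard_stratum))
        outcome.overall_cluster_specific.append(cs.final_f1())
        outcome.overall_random.append(rnd.final_f1())
        results.extend([cs, rnd])
    return outcome, results
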