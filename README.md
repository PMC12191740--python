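# hilcell

Cluster-based human-in-the-loop sampling for circulating-tumor-cell
classification on learned image embeddings.

## The problem

Circulating tumor cells (CTCs) are rare tumor-derived cells in the blood of
metastatic cancer patients (fewer than 10 per mL). The clinical standard
detects them by immunofluorescence: enriched cells are imaged in three
channels (DAPI nuclear stain, cytokeratin/CK tumor marker, CD45 leukocyte
marker) and a trained reviewer confirms each candidate by eye. A binary
classifier on learned single-cell image embeddings can automate most of this
triage, but its errors are not spread evenly over the embedding space — they
concentrate in particular latent-space regions, and expert labeling time is
the scarcest resource for fixing them.

`hilcell` implements a targeted human-in-the-loop (HiL) annotation strategy
for this setting, for anyone building or maintaining an embedding-based cell
classifier with a limited labeling budget:

1. the latent space is reduced (PCA), projected to 2-D (UMAP), and density
   clustered (HDBSCAN); points in no cluster form an explicit *background*
   stratum;
2. the classifier's F1 score is computed per stratum, s_i;
3. new samples to label are drawn from stratum i with frequency

       c_i = (1 − s_i) / Σ_j (1 − s_j),

   i.e. inversely proportional to local performance, so the expert's time
   goes where the classifier is weakest;
4. labeled samples join the training pool and the loop repeats (4 loops by
   default, each arm repeated over seeds).

The package ships three experiment engines that benchmark this strategy
against random sampling (globally scarce labels; locally scarce labels for
one cluster; a budgeted labeling oracle on unlabeled data), a synthetic-data
module that generates clustered Gaussian embeddings with a tunable hard
cluster plus synthetic three-channel cartridge images, crop extraction,
an SVM classifier contract with a noise pre-filter, and candidate-triage
reporting (threshold, duplicate removal, positive predictive value).

## Worked example

```python
import numpy as np
from hilcell import study

# synthetic study: 5 embedding clusters x 300 cells, one cluster "hard"
# (class separability 0.5 SD vs 5.0 elsewhere); PCA to 32 dims, joint
# UMAP + HDBSCAN clustering of the unlabeled-train + test latent space
setup = study.prepare_study()
print(f"clusters found: {setup.n_clusters}, hard stratum: {setup.hard_stratum}")

# scenario 1: start from 100 labels, add 100 per loop for 4 loops,
# cluster-specific (inverse-F1) arm vs random arm, 5 paired seeds
outcome, runs = study.run_paired_scenario1(setup, seeds=[1, 2, 3, 4, 5])
print(f"  cluster-specific: {np.mean(outcome.cluster_specific):.3f} "
      f"+/- {np.std(outcome.cluster_specific):.3f}")
print(f"  random:           {np.mean(outcome.random):.3f} "
      f"+/- {np.std(outcome.random):.3f}")
```

prints

```
clusters found: 5, hard stratum: 3
  cluster-specific: 0.630 +/- 0.015
  random:           0.507 +/- 0.036
```

Reading: the density clustering recovers all five generated clusters; the
hard cluster (overlapping classes, initial F1 ≈ 0.47) ends four loops at
F1 0.630 when the labeling budget is steered by inverse-F1 weights, versus
0.507 when the same budget is spent at random — the targeted strategy
repairs the weak region substantially faster at equal annotation cost.

A command-line interface wraps the same steps:

```
hilcell synth --out emb.csv                      # synthetic embedding table
hilcell cluster --embeddings emb.csv --out strata.csv
hilcell run --scenario s1 --embeddings emb.csv --strata strata.csv --out run/
hilcell apply --embeddings emb.csv --out gallery/   # candidates + PPV table
```

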