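# Methods

## Model and procedure

`hilcell` treats binary CTC / non-CTC classification on learned single-cell
image embeddings as a *locally* evaluated problem. The embedding space is
reduced by PCA (default 32 components of a 128-dim representation),
projected to 2-D with UMAP, and density-clustered with HDBSCAN. Points that
HDBSCAN assigns to no cluster are kept as an explicit background stratum
(label −1) with the same standing as any cluster: it is evaluated and may
receive annotation effort.

Clustering runs on the joint unlabeled-training + test latent space. The
reasoning: at application time, new (non-training) samples must be
assignable to a stratum, so held-out data has to participate in the cluster
geometry; the larger unlabeled pool also stabilizes cluster shapes that a
small labeled test set would represent poorly. Labeled training points,
which are not part of the joint set, are assigned the stratum of their
nearest joint-clustered neighbor in the 2-D plane (out-of-sample UMAP
transform followed by a 1-NN lookup).

Per-stratum classifier performance is the F1 score computed from the
stratum's pooled confusion counts, with two degenerate conventions:

* TP = FP = FN = 0 → F1 = 1 (a stratum with no positives anywhere and no
  false alarms is solved, so it should attract no labeling effort);
* otherwise TP = 0 → F1 = 0.

The sampling rule converts per-stratum scores s_i into draw frequencies

    c_i = (1 − s_i) / Σ_j (1 − s_j),

with a uniform fallback when every s_i = 1. Draw counts are realized by a
seeded multinomial draw (honoring "frequency" rather than deterministic
rounding); a stratum whose candidate pool is exhausted forfeits its excess,
which is re-allocated among the remaining strata by renormalized weights
until the budget or the total pool is spent.

During the budget-limited experiment, the s_i used for sampling come from a
Monte-Carlo cross-validation of the current (small) training pool: 100
folds of unstratified 90/10 train/validation splits, validation predictions
pooled across folds into per-stratum confusion counts, F1 computed once on
the pooled counts. Unstratified splitting is deliberate — it reflects the
sampling randomness of a real annotation workflow — so a fold's training
half can occasionally be single-class; such a fold predicts its one
observed class for all its validation points rather than aborting. An
alternative combination (mean of per-fold F1 instead of pooled counts) is
available via `combine="mean"`. The F1 trajectories that the experiments
*report* always come from the held-out test set; the MC estimate only
steers sampling.

## Experiment engines

All engines run two arms from the same initial pool per seed and record
per-loop per-stratum and overall test F1 (loop 0 = initialization, 4 loops
by default, 5 seeded repeats by default).

* **Scenario 1 (limited global data):** initial pool of 100 labeled
  samples; each loop adds 100 — drawn per-stratum by the inverse-F1 rule
  (cluster-specific arm) or uniformly from the whole relabeling pool
  (random arm) — ending at 500 after four loops.
* **Scenario 2 (limited local data):** one *main cluster*'s labeled
  training data is pruned to 20% of its size, all other strata to 80%. The
  cluster-specific arm restores the main cluster in 20% increments (a fixed
  random order) until 100% is used. The random arm draws the same per-loop
  counts from a reservoir holding, for every stratum, a slice of its
  left-out samples amounting to 20% of the stratum's original labeled size.
* **Real-world:** the initial pool is the full labeled training set; a
  relabeling pool of 1,000 samples is drawn from the (noise-filtered)
  unlabeled training data. Each loop, the cluster-specific arm presents
  predicted-negative members of the target cluster to a budgeted oracle
  (default 11 queries per loop) standing in for a time-limited human
  expert; confirmed positives join the pool as new CTC examples. The
  random arm queries randomly ordered predicted negatives of any stratum
  until it has confirmed the same number of positives as the
  cluster-specific arm that loop (or its pool is exhausted), so both arms
  add matched counts. Because each seed re-queries the oracle, repeats are
  true re-runs rather than shuffles of one run's findings.

Background is eligible for cluster-specific sampling by default
(`include_background_in_sampling`); it carries an F1 like any stratum, and
excluding it is a config switch rather than a hard rule because the
evidence for either convention is thin.

## Synthetic data

`synthdata.generate_latent_dataset` emulates the latent structure the
pipeline consumes: isotropic unit-variance Gaussian clusters in D dims
(default 128) whose positive/negative class means are pulled apart by
`separability` within-class SDs along a single random unit axis shared by
all clusters (the class contrast is a property of the representation, not
of individual clusters; a shared axis also makes the high-separability
limit genuinely linearly separable). Cluster centers sit on a scaled
simplex with pairwise distance 8 SD *plus* the largest class offset, so
clusters remain distinct however separable their classes are. Optional
background points are uniform over the data's bounding box; optional noisy
points are Cauchy-tailed outliers (flagged, giving the noise filter
something learnable).

The standard study conditions (`cli.hard_cluster_dataset`,
`study.prepare_study`) are five clusters of 300 points in 128 dims, class
mixes (0.7, 0.3, 0.8, 0.2, 0.5), separability 5.0 except 0.5 in the hard
cluster, 5% background, splits 50% labeled-train / 25% unlabeled-train /
25% test. These sizes keep a full 10-seed paired experiment within a few
minutes on one CPU while leaving the hard cluster genuinely hard (its
Bayes-optimal F1 is well below 1).

What the generator does *not* emulate: real embedding manifolds are not
Gaussian mixtures, class boundaries are not linear offsets, artifact modes
(shine-through, smears) have structure rather than heavy tails, and
patient-level batch effects are absent. Passing tests therefore demonstrate
that the machinery — clustering, weighting, bookkeeping, the benefit of
targeted sampling when errors concentrate in a recoverable region — works
as designed; they do not certify performance numbers on clinical data.

The cartridge generator renders Gaussian-blob cells at the scanner's tile
geometry (1,036 × 1,384 px): every cell bright in DAPI, a configurable
subset bright in CK (CTC-like), the rest bright in CD45 (leukocyte-like),
with a disk instance mask and a truth table. Placement retries up to 200
positions per cell and raises if the tile cannot hold them without overlap.

## Classifier and candidate handling

The classifier contract is a margin model with calibrated probabilities:
an RBF-kernel SVM at library defaults with probability output,
deterministic tie-breaking, and balanced class weighting by default (CTCs
are rare; balanced mode reweights classes inversely to frequency).
Candidate proposal keeps points with probability strictly above the
threshold (default 0.5), then removes duplicates: candidates whose
centroids lie within a radius (default 5 px, roughly one cell diameter) of
each other — closed transitively — are collapsed to the highest-probability
member, ties broken by lowest id. PPV is reported to 3 decimals;
a sample with zero suggested candidates reports a missing PPV rather
than 0. Totals in PPV tables are always recomputed from the rows.

## Numerical choices

* PCA is an eigendecomposition of the sample covariance of centered data;
  components are ordered by decreasing eigenvalue and signed so each
  component's largest-magnitude coordinate is positive — refits are
  bit-identical.
* A constant crop channel (max = min) normalizes to all zeros ("no
  signal"); crop windows at image borders are zero-padded, never clipped,
  so crop counts and shapes are conserved. Centroids are unweighted means
  of instance pixels, rounded toward zero, 0-based (row, col).
* UMAP defaults: n_neighbors 15, min_dist 0.1, fixed seed (which forces
  single-threaded, reproducible embeddings). HDBSCAN min_cluster_size
  defaults to max(25, N/200). These are common defaults; the experiments
  pin behavior on synthetic data only.
* All randomness flows through `numpy.random.Generator` objects seeded per
  run and per arm; a fixed seed reproduces selected ids and confusion
  counts bit-for-bit.
* An all-identical-coordinates input to the density clusterer returns a
  single cluster covering everything (HDBSCAN cannot build a hierarchy on
  zero spread); this degenerate behavior is pinned by a regression test.

## Known limitations

* The expert's wall-clock labeling budget is modeled as a query count
  (default 11 per loop, configurable); real labeling throughput varies
  with image difficulty.
* Out-of-sample stratum assignment depends on UMAP's transform, which is
  approximate near cluster boundaries.
* The directional advantage of cluster-specific sampling is a property of
  error concentration: on data whose errors are already uniform across
  strata, the two arms coincide in expectation, and on small pools the
  paired comparison at 10 seeds can fail to reach significance for
  individual dataset realizations even when the mean effect is positive.
* Scenario 2's random-arm reservoir interpretation (a 20%-of-original-size
  slice per stratum) is one reading of an underspecified design; the
  matched per-loop counts, which drive the comparison, do not depend on it.
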