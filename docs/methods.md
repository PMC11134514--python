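# Methods

## The problem

In few-shot bioactivity prediction, a model must classify molecules as
active or inactive against a protein target given only a handful of
labeled examples, typically by transferring knowledge from a pool of
related assay tasks. Whether that transfer helps varies sharply from task
to task. `taskhard` assigns each target task a *hardness* score built from
three signals: how far the target's labeled chemistry sits from the source
pool (EXT_CHEM), how far its protein sits from the source proteins
(EXT_PROT), and how hard the task is for a few-sample single-task model in
isolation (INT_CHEM). The score is validated by its anti-correlation with
the gain a prototypical-network meta-learner achieves over single-task
baselines.

## Chemical-space distance (OTDD)

Two tasks' molecule sets are compared with the optimal transport dataset
distance. Each molecule is a feature vector `x` (RDKit 2D descriptors or a
loaded pretrained embedding) with a binary label `y`. The ground cost
between molecule–label pairs is

    d((x, y), (x', y'))^2 = ||x - x'||^2 + W2(alpha_y, alpha_{y'})^2

with `alpha_y` the within-dataset feature distribution of label `y`,
modeled as a Gaussian; the label term is then the closed-form Bures
2-Wasserstein distance. The dataset distance is the square root of the
optimal transport cost between the two empirical distributions with
uniform marginals. Order p = 2 throughout: the closed form for the label
term exists only there, and the square root restores the original feature
scale (the distance is 1-homogeneous under joint feature scaling when
covariance shrinkage is off, a property the tests check).

Numerical choices:

- **Class Gaussians.** Mean and covariance use denominator n (not n − 1)
  so singleton classes are well-defined; covariance is regularized by
  `shrinkage * (trace/d) * I` (default shrinkage 1e-3) plus an absolute
  floor of 1e-8·I, because real assay tasks can have fewer actives than
  feature dimensions. Matrix square roots go through symmetric
  eigendecomposition with negative eigenvalues clipped at zero, and a
  Bures trace term below a relative noise floor of 1e-9·(trΣ₁+trΣ₂) is
  treated as exactly zero (roundoff from near-identical covariances).
- **Solvers.** Instances up to 250 000 cost entries use the exact solver:
  uniform square marginals reduce to the assignment problem (a vertex of
  the Birkhoff polytope is optimal), anything else goes through the HiGHS
  LP. Larger instances use log-domain Sinkhorn with
  `epsilon = 0.1 * mean(cost)` by default. The Sinkhorn plan is rounded
  onto the coupling polytope before the cost is reported, so the reported
  value is a true upper bound on the unregularized optimum rather than the
  cost of a slightly infeasible plan.
- **Subsampling.** Tasks above 1000 molecules are subsampled stratified by
  label (seed recorded in the distance-matrix metadata). Degenerate
  single-class datasets are allowed; the label-pair Wasserstein table only
  covers pairs that occur.
- **Standardization.** Whether molecule features are standardized before
  OTDD is exposed as a flag and recorded in the matrix metadata; 2D
  descriptors (whose scales span orders of magnitude) default to
  standardized, loaded pretrained embeddings default to raw.

## Protein-space distance

Proteins are embedded by mean-pooling per-residue token vectors. The
built-in embedder uses the 21-way residue one-hot plus a normalized 2-mer
count profile (462 dims, deterministic, no model download); pretrained
protein language-model vectors are loaded from per-task files. Distances
are Euclidean by default (cosine behind a flag) on the raw mean-pooled
vectors — no length normalization, and that choice is recorded in the
matrix metadata. Target tasks must be single-protein; a source task that
is a protein complex contributes the **largest** member distance, the most
pessimistic view of the target's proximity to the complex. Sources without
any sequence are excluded from the protein matrix (logged).

## Hardness components and combination

- **EXT_CHEM** per target: difficulty-weighted mean OTDD over the k = 10
  nearest sources. Each source's difficulty is its own internal hardness
  (random forest, 16 training samples) — near sources that are themselves
  unlearnable should not count as useful neighbors. Weights are
  renormalized within the selected neighborhood (the global alternative
  would let far, easy sources dilute the neighborhood signal).
- **EXT_PROT** per target: plain mean protein distance over the k nearest
  sources.
- **INT_CHEM** per target: 1 − ROC-AUC of a random forest (500 trees,
  class-balanced; kNN k = 5 as alternative) trained on m_train = 16
  stratified samples, validated on the remainder. Splits leaving one side
  single-class are re-drawn up to 10 times. Random and Bemis–Murcko
  scaffold splits are available; the scaffold split assigns scaffolds by
  descending member count to the training side until m_train is reached.
- **Combination.** Each component is min-max normalized across the target
  collection of one run (all-equal components map to zero), then summed
  with user weights (equal by default; a zero weight skips a component and
  its inputs entirely). Normalization scope is recorded in the report's
  provenance, so reports from different runs are not accidentally
  comparable.
- **Ties** in k-nearest selection and source ranking break by ascending
  task id — deterministic and order-independent.

## Prototypical network

The meta-learner encodes molecules with a feed-forward network (default
two hidden ReLU layers of 128 units into an 8-dim linear output), computes
class prototypes as encoded support means, and classifies query molecules
by softmax over negative squared Euclidean distances. Training is
episodic: each step samples one source task, draws a stratified
16-support/64-query episode, and takes an Adam step (lr 3e-3, 1000
episodes) on the query cross-entropy; gradients are computed by manual
backpropagation through the prototype construction. The narrow output
keeps the representation concentrated on directions that discriminate
activity across many source tasks, which is what makes the encoder's
benefit task-relatedness-dependent. Encoder inputs are standardized with
statistics pooled over the source tasks.

A single episodic training run of a small encoder is noisy, so the
pipeline evaluates an ensemble of three independently seeded encoders and
averages metrics over eight episode draws per task (the plain
`evaluate_task` API defaults to five draws). With an identity encoder the
model reduces exactly to nearest-class-centroid classification with
softmax probabilities, which the tests use as an oracle. The single-task
baselines (random forest, kNN) fit on the episode support only; the random
forest evaluation at support size m reproduces the INT_CHEM split exactly
(same seeds), tying the two modules together.

## Synthetic benchmark

The generator plants ground truth that the pipeline must recover:

- Each task draws 200 molecule vectors (16-dim) from a 4-component
  Gaussian mixture around a *chemistry anchor* (anchor scale 4, cluster
  spread 1.5, within-cluster spread 1), labels them by a task-specific
  linear rule thresholded at the median projection (guaranteeing
  near-balanced classes), and flips each label with probability 0.05 — a
  realistic assay-noise floor.
- A target with relatedness `rho` shares its chemistry anchor, protein
  anchor (32-dim), and label rule with `ceil(rho * 10)` designated source
  tasks; the rule is the unit-normalized convex combination
  `rho * w_family + (1 - rho) * w_random`, so the rule angle degrades
  smoothly as relatedness drops. Targets with the same `rho` level share
  one family so the designated sources fit inside the default 50-source
  universe; `rho = 0` targets share nothing with any source.
- The default universe: 50 sources, 20 targets at relatedness levels
  {0, 0.25, 0.5, 0.75, 1} × 4, seed 7 — sized so the full pipeline
  (distances, hardness, ensemble protonet evaluation) finishes in a few
  minutes on one CPU.

What the generator does **not** emulate: real chemical-space geometry
(molecules are feature vectors; the SMILES in generated task files are
inert surrogates), assay heterogeneity, activity-threshold artifacts,
scaffold structure, or class imbalance. Passing recovery tests therefore
shows that the statistical machinery behaves as designed — distances
recover planted relatedness and hardness predicts transfer gain *when the
planted structure is the only structure* — not that the same effect sizes
will appear on any particular real assay collection.

The recovery report checks: Pearson correlation between planted
relatedness and each hardness component; correlation between combined
hardness and the prototypical network's AUPRC gain over the random
forest; and a permutation control reported as the mean absolute
correlation between shuffled relatedness and EXT_CHEM over 20 seeded
permutations (a single 20-element permutation has a correlation standard
deviation near 0.23, so one draw would be an unstable null check).

The source-selection experiment trains, per target, prototypical networks
on the 10 sources ranked nearest by the summed normalized chemical and
protein distance columns, against networks trained on 10 randomly drawn
sources (5 draws), each arm ensembled over 3 encoder seeds, and reports
the fraction of targets where rational selection is at least as good.

## Known limitations

- The exact LP solver is dense; it is intended for desk-scale instances
  (the auto threshold hands larger problems to Sinkhorn).
- OTDD with Gaussian label models ignores multi-modality within a label
  class beyond what the covariance captures.
- Duplicate molecules within a task are kept as-is (their weight in the
  empirical distribution doubles); deduplication is left to the caller.
- The built-in protein embedder captures composition and local order only;
  it is a deterministic stand-in interface for pretrained language-model
  embeddings, not a competitive representation.
- Hardness normalization is collection-relative: a score is meaningful
  only within the run that produced it.
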