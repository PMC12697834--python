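# Methods

## The classification model

Each ROI (one DNA-origami structure) or cell is represented as a hierarchical
graph. Localization nodes carry only a position; each belongs to exactly one
cluster node. Cluster nodes carry the centroid of their members and,
optionally, a feature vector. Undirected edges (stored symmetrically, one
self-loop per node) join each cluster node to its five nearest neighbours in
the normalized frame. Node positions are normalized per graph to [−1, 1] with
a shared divisor for x and y, preserving aspect ratio; absolute scale is
deliberately discarded, so classes must differ in shape and in the (scale-
carrying) cluster features rather than in raw extent.

ClusterNet applies four message-passing layers with PointTransformer-style
vector attention over the cluster graph. For an edge j → i with node
features x and positions p:

    δ_ij = θ(p_j − p_i, ‖p_j − p_i‖)          (two-layer MLP)
    e_ij = γ(q(x_i) − k(x_j) + δ_ij)          (two-layer MLP, per channel)
    α_ij = softmax over j ∈ N(i) of e_ij
    y_i  = Σ_j α_ij ⊙ (v(x_j) + δ_ij)

with q, k, v linear. Each block is `x ← relu(LN(conv(x))) + x` (LayerNorm,
residual). Only relative positions enter, so the layer is translation
invariant; it is *not* rotation invariant — rotation robustness is learned
from augmentation. The position MLP additionally receives the relative
distance ‖Δp‖: that component is rotation invariant, which speeds up
learning of rotation-robust geometry at small sample sizes without removing
the raw relative vector's expressiveness. Global readout is an elementwise
maximum over cluster nodes, followed by one linear layer and log-softmax.

Cluster input features come in two modes. HCF uses the eight handcrafted
features (below), min-max normalized to [0, 1] with statistics measured on
the training set only; out-of-range values at test time are clamped so the
model's input domain stays fixed. LCF computes an 8-dimensional embedding
per cluster with LocNet — the same attention convolution applied to the
cluster's member localizations (k = 8 nearest members + self), two blocks,
max-pooled over members, squashed to (0, 1) with a sigmoid — trained end to
end with ClusterNet as one network. Member localizations have no input
features; a constant is lifted to the hidden width and geometry enters only
through the position encodings, keeping LocNet translation invariant and
permutation invariant by construction.

Widths are configurable; defaults (hidden 64 for ClusterNet, 16 for LocNet,
embedding length 8, 4 message-passing layers, 2 LocNet blocks) are this
package's own choices, picked for single-CPU training, not reference values.

## Handcrafted features

For a cluster with ≥ 3 non-collinear localizations: count; radius of
gyration squared (mean squared distance from the centroid, nm²); convex-hull
perimeter (nm); and from the eigenvalues λ₀ ≥ λ₁ of the sample covariance
matrix of the coordinates: linearity (λ₀−λ₁)/λ₀, planarity λ₁/λ₀, length
2.35·√λ₀ (the FWHM of a Gaussian with variance λ₀; the constant is used as
the literal 2.35, not 2√(2 ln 2)), area 2.35²·√(λ₀λ₁), density count/area.
In 2D, λ₂ = 0 and linearity + planarity = 1; the redundant feature is kept —
it costs nothing and keeps the vector length at eight. The covariance uses
the n − 1 denominator by default (standard PCA convention; `ddof=0`
available). Collinear clusters have zero area and hence undefined density;
they raise a degenerate-input error rather than returning infinities —
upstream small-cluster filtering makes them rare. Localizations are not
precision-weighted.

## Preprocessing

Quality cuts (defaults): photons ≤ 30 000, PSF σ in [75, 200] nm, PSF fit
p-value ≤ 0.01, precision ≤ 25 nm; thresholds on absent columns are skipped
with a warning. Temporal grouping chains localizations within 60 nm and at
most 2 frames apart into tracks (greedy, transitive, nearest candidate from
the track's last member); tracks spanning ≤ 5 frames collapse to one
localization at the unweighted mean with the first frame number, longer
tracks are removed. Cells are cut out of fields of view with pre-made
polygons; localizations within half the membrane-band width (default 100 nm
band) of a membrane polyline are labeled `membrane`, others `interior`;
cells with < 500 localizations or < 5 membrane or < 5 interior localizations
are dropped. Clustering is k-means (k-means++ init, 10 restarts, seeded;
default k = 12) or DBSCAN (ε, minPts; noise excluded downstream); clusters
with ≤ 2 localizations are discarded so the hull and PCA exist. Rows are
lexicographically sorted before clustering so the partition does not depend
on input row order. All filters are idempotent.

## Training and evaluation

Adam, learning rate 10⁻³, weight decay 10⁻⁴ (classic L2-added-to-gradient),
negative log-likelihood on log-softmax outputs, batch size 128 (8 for
cell-scale datasets), a weighted random sampler with per-item weight
1/count(class) so expected class frequencies are equal, and a random
in-plane rotation of each sampled graph (one angle per graph per draw,
features and topology untouched). After each epoch the model is evaluated on
the validation set without augmentation; the checkpoint with minimum
validation loss over all epochs is returned (no early stopping). Divergence
(non-finite loss) aborts with a diagnostic.

Partitions: stratified five-fold cross-validation (per fold: disjoint 20%
test, then 64%/16% train/validation of the whole, all stratified) or grouped
cross-validation where groups (patients) are assigned whole to folds by a
greedy balance of fold size and class ratio; the validation split within a
grouped fold also keeps groups whole. Metrics: per-class recall, balanced
accuracy (arithmetic mean of recalls; classes absent from a test set yield
NaN recall with a warning and are excluded from the mean), one-vs-rest AUROC
per class plus macro average, confusion matrix. Ties in argmax
classification go to the lowest class index.

## Explainability

Feature embeddings are extracted at four levels (handcrafted, LocNet,
post-final-message-passing, pooled whole-graph), normalized per feature by
subtracting the mean and dividing by the variance measured over a designated
reference set (everything except a reserved test set, typically). Dividing
by the variance rather than the standard deviation is the pipeline's literal
convention; `normalization="std"` switches to ordinary z-scoring. UMAP
(2 components, 20 neighbours, min_dist 0.5, seeded) produces the 2D views.

SubgraphX searches for the most important connected subgraph of at most 8
cluster nodes using Monte-Carlo tree search (100 rollouts by default). The
root is the full node set (per connected component); each action removes one
node while preserving connectivity; every visited candidate-sized subset is
scored by a sampled-Shapley contribution: coalitions are drawn from the
2-hop neighbourhood of the candidate (each neighbour included with
probability ½, 100 draws by default) and the score is the mean of
p(S ∪ C) − p(C) for the predicted class, with the empty occlusion assigned
the uniform distribution. The score of a given subset is a deterministic
function of (subset, seed), making scores comparable across candidates and
runs. Selection uses UCT with deterministic tie-breaks; the rollout reward
is the best candidate score on the path. Occlusion deletes nodes and their
incident edges and keeps the original normalized positions of the remainder
(re-normalizing would confound occlusion with geometry change); member
localizations follow their cluster. Fidelity uses the same induced-subgraph
construction: Fid⁺ = p_full − p(complement), Fid⁻ = p_full − p(subgraph),
both anchored on the model's predicted class for the full graph, undefined
(reported as None) when the respective node set is empty.

## Synthetic data

The generator emulates DNA-PAINT origami ROIs: a class is a layout of
binding sites; digits are continuous strokes on a 5×7 dot matrix at 13 nm
pitch (10–14 sites), letters are few well-separated site groups, and the
grid is a 3×4 lattice of 12 sites. Per retained site, a Poisson(30) number
of localizations scatter with isotropic Gaussian σ = 3 nm (typical DNA-PAINT
precision); each site independently drops out with probability 0.05
(misfolded structures); Poisson(10) uniform background localizations per
200×200 nm ROI model spurious detections; each ROI lands in a uniformly
random orientation, as origami do on a coverslip. Seeds fully determine
output; per-ROI seeds are spawned from the master seed.

Not emulated: blinking kinetics and camera noise (counts per site are
i.i.d. Gaussian, not time-correlated), localization-precision heterogeneity,
drift residuals, 3D. Passing tests on this generator therefore demonstrate
that the pipeline recovers class structure from cluster shape, supracluster
arrangement and realistic nuisance (background, misfolds, rotation) — not
that it is robust to photophysical artifacts of real acquisitions.

## Numerical choices and problem sizes

The neural network runs on a small reverse-mode autodiff engine over float32
numpy arrays with sort-based segment kernels and a fused attention op whose
backward pass was verified against finite differences. Forward passes are
deterministic given seeds on a fixed platform; across BLAS implementations
results may differ at float32 rounding level. k-nearest-neighbour ties
(cluster edges, LocNet neighbourhoods) break by lowest index. The held-out
recovery experiment in the test suite uses 4 classes × 200 synthetic ROIs,
k-means k = 12, 50 epochs at batch 128 — sizes chosen so the whole suite
runs on one CPU in minutes while leaving the training protocol itself
untouched.

## Known limitations

- The grouped-CV greedy balancer approximates, not optimizes, the class
  ratio across folds.
- SubgraphX cost grows quickly with graph size (Shapley sampling per
  candidate); for graphs beyond a few dozen clusters, reduce rollouts or
  Shapley samples.
- Temporal grouping links transitively from the track's last member;
  linking to the running mean is a plausible alternative the implementation
  does not currently offer.
- 3D data, precision-weighted features and multi-level cluster hierarchies
  are out of scope.
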