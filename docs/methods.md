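# Methods

This note records the modelling choices, defaults, numerical conventions and
known limitations of `protfuse`, in the spirit of a model-description
appendix. Nothing here states an empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Structures and their symmetries

A parsed structure keeps heavy protein atoms only: HETATM records (waters,
ligands, ions) and hydrogens are excluded, so point clouds describe the
protein itself and the residue graph is anchored on alpha carbons. Alternate
locations collapse to the first-occurring conformer; chains are concatenated
in file order with a globally unique residue ordinal; residues lacking a CA
are dropped from the sequence (and the graph) but their atoms remain in the
point cloud. Non-standard residues map to an "unknown" amino-acid class.

The package treats the three fundamental nuisance symmetries explicitly:

* **Rigid motions.** Residue-graph construction uses only pairwise CA
  distances, so edge sets are exactly invariant. Point-cloud
  standardization removes translation (centering) and global size
  (unit-sphere scaling) but deliberately *not* rotation; rotation
  robustness is learned by the point autoencoder through augmentation.
* **Permutations.** The PointNet encoder is exactly permutation invariant
  (element-wise max over points); the GCN encoder is permutation
  *equivariant* (relabeling nodes relabels latents).
* **Scaling.** Uniform coordinate scaling of the input is removed by the
  unit-sphere normalization.

## Residue graphs

Nodes carry a 21-way one-hot (20 standard residues + unknown). Each node
selects its k = 5 nearest neighbours by CA Euclidean distance; distance ties
at the k-th neighbour break deterministically toward the lower residue
index; the directed selections are unioned into an undirected, unweighted
edge set (the graph autoencoder is defined for undirected graphs; whether
the original KNN recipe directed or deduplicated edges is an open choice —
union-symmetrization is ours). Distances are double precision in Å; no
cutoff radius is applied beyond the k-th-neighbour threshold. For
structures with fewer than k+1 residues, k is capped at N−1.

## Graph VAE

Encoder: H₁ = ReLU(Â X W₁) with Â = D̃^{-1/2}(A+I)D̃^{-1/2}, then
μ = Â H₁ W_μ and log σ² = Â H₁ W_logvar. Widths: hidden H = 1024, latent
D = 640 — D is forced by the fusion stage's requirement that all three
modality vectors share one dimensionality; H is a free choice. No biases,
matching the plain GCN formulation. Latents are sampled by
reparameterization during training; evaluation always uses μ.

The loss is the *summed* cross-entropy over positive edges and an equal
number of freshly sampled negative non-edges per step (balanced sampling;
on very dense small graphs the negative count is clamped to the number of
available non-edges). The KL term of the classic formulation is
intentionally omitted: the latent serves as a structural representation,
not a generative prior. Optimizer: Adam, lr 1e-3, one full-graph step per
graph per epoch, 100 epochs by default.

**Edge dropout.** At every training step a random 10% of the graph's edges
is hidden from the propagation matrix while the loss still scores all
positives. Without this, the objective degenerates into adjacency echoing —
the decoder can read an edge's presence directly off the messages passed
along it — and held-out-edge prediction stalls; hiding edges makes training
match the link-prediction task the model is evaluated on. The 10% rate
mirrors the evaluation holdout fraction.

**Evaluation protocols.** Two are provided. `evaluate_link_prediction`
scores *unseen* graphs: 10% of each test graph's edges are held out, the
remnant is encoded, and held-out positives compete with equal-count sampled
non-edges (pooled AUC / average precision). `link_prediction_benchmark` is
the canonical transductive protocol: edges are held out up front, training
sees only the remnants, and the held-out edges are scored at the end. The
benchmark is the headline pretraining metric; the inductive variant is what
the pipeline logs for its test split. Holdout resampling retries until the
remnant is connected (up to 50 draws).

## Point clouds and the point autoencoder

Standardization order is center → scale → pad/trim. Padding appends zero
rows (which sit at the centroid after centering); trimming keeps the first
M atoms in record order (an optional seeded uniform subsample is available).
M defaults to 2048 for the standalone converter; the pipeline default is
M = 256, matched to the size of the synthetic structures it trains on.

Encoder widths are 3→64→128→640 (vanilla PointNet scaled to a 640-dim
code); there are no spatial-transformer blocks — orientation is handled by
augmentation, keeping the permutation/rotation story clean. Decoder:
640→512→256→256→3M with ReLU + batch normalization after each hidden layer
and a linear output reshaped row-major to M×3.

Batch normalization uses batch statistics during training (momentum 0.9
running averages for evaluation). Batch statistics are undefined for a
single-sample batch; in that case the layer passes activations through
(affine transform only) and leaves running statistics untouched, so
single-cloud training remains well-posed and evaluation stays consistent.

Training: Adam (lr 1e-3), mini-batches of 8 clouds, a fresh Haar-uniform
rotation (normalized 4-dim Gaussian quaternion) applied to the real points
of every cloud at every step; padding rows are never rotated. Padded zeros
participate in the chamfer loss by default (a mask flag exists, off by
default). The chamfer distance is exposed in both summed and per-point-mean
reductions; the summed form is the default and the training loss.
Evaluation decodes unrotated clouds with frozen normalization statistics.

## Sequence embedding

The offline embedder concatenates 21 composition frequencies and 441
normalized 2-mer frequencies, zero-padded to 640 — deterministic, order
sensitive through the 2-mers, and sufficient for exercising the pipeline.
The language-model adapter accepts any handle exposing per-residue last
hidden states of width 640 and mean-pools them over residue positions (how
per-token states become one protein vector is not canonical; mean pooling
is the choice here and is isolated behind the interface). The adapter
raises a capability error when no checkpoint is available; no test or
script requires one.

## Fusion

The graph branch's node-latent matrix is pooled by top-k: nodes ranked by
the L2 norm of their μ row (ties toward the lower index), the top
min(N, 640) rows averaged. Proteins with fewer than 640 residues average
all nodes — zero-padding fake nodes would bias the mean toward zero. The
pooled graph vector, the sequence vector and the cloud code are z-score
normalized per dimension with statistics fit on the 70% training split
only. A dimension with no training variance carries no calibrated scale,
so it maps to exactly 0 for any input rather than being divided by the
variance floor (1e-8), which would explode on unseen data.

Auto-Fusion concatenates (sequence, graph, cloud) — the order is fixed and
recorded — and trains 1920→1280→640→1280→1920 with tanh hidden activations
under mean-squared reconstruction error: Adam, lr 1e-3, mini-batches of 32,
optional per-epoch learning-rate decay (default off; the single-triple
memorization test uses it to anneal Adam's step-size jitter). Loss
histories include the untrained model's MSE at index 0 as the baseline.

### The shared-factor surrogate

The fusion learning check uses synthetic triples: a 640-dim factor per
protein observed through three fixed random orthogonal mixings plus
independent Gaussian noise (σ = 0.5). The factor lies on a fixed random
32-dimensional subspace. This intrinsic rank matters: with a full-rank
isotropic 640-dim factor and only 200 samples, no method can reconstruct
validation items (140 training samples span at most 140 of 640 factor
directions), whereas large-corpus pretraining operates with sample counts
that dwarf the embedding width. Rank 32 restores that regime at desk scale.
For the same reason the factor probe — does the fused latent linearly
encode the factor? — is a cross-validated ridge regression fit and scored
in-sample: an out-of-sample 640→640 linear map is unidentifiable from 200
samples. The cross-validated penalty keeps the probe discriminative
(uninformative latents select a large penalty and score near zero; this is
verified against a random-latent control in the test suite).

## Downstream heads

Affinity: features are the fused protein vector concatenated with a Morgan
fingerprint (radius 2, 2048 bits — the ECFP4-equivalent convention).
Feature columns are standardized before the kernel: the embedding and
fingerprint blocks live on very different numeric scales, and an isotropic
RBF kernel on raw features lets the larger-scale block dominate the metric,
which drives the marginal-likelihood optimizer into a degenerate
zero-length-scale solution. The RBF length scale starts at the median
pairwise training distance; the kernel is ConstantKernel × RBF + White,
targets standardized internally. Classifier: gradient-boosted trees
(300 trees, depth 6, lr 0.1, seeded); stability pairs concatenate
wild-type and mutant vectors.

Concordance index: pairs with tied true labels are excluded; tied
predictions score half — the dominant convention in the affinity
literature. rm² uses the through-origin scaling k = Σyŷ / Σŷ² for r₀².

## Synthetic data

`make_helix` places CA atoms on an ideal α-helix (rise 1.5 Å/residue,
100°/residue, radius 2.3 Å — textbook geometry used as a synthetic
stand-in, not a biological claim) with 1–4 dummy side-chain carbons per
residue (count keyed to residue type) and isotropic Gaussian coordinate
noise, default σ = 0.3 Å — enough to break distance ties generically.
Sequences are uniform over the 20 standard amino acids. Dataset defaults:
60 structures of 30–60 residues. The affinity task crosses each protein
with ten hand-written ligand SMILES; labels are a seeded linear function of
sequence composition (weight ×10) plus a per-ligand offset, optionally with
Gaussian noise — learnable by construction, so head failures indicate
pipeline defects rather than label noise.

What the fixtures do *not* emulate: realistic secondary-structure
diversity (everything is helical), side-chain chemistry and packing,
Ramachandran validity, long-range tertiary contacts, or binding physics.
Green tests therefore certify the machinery — symmetries, losses,
optimization, determinism, end-to-end plumbing — not biological accuracy
on real proteins.

## Problem sizes and numerical conventions

Desk-scale defaults keep every training run on one CPU core: 60 structures,
graphs of 30–60 residues, clouds of M = 128–256 points, 100 pretraining
epochs for the headline runs and 5–20 epochs for the end-to-end smoke
configuration. Probabilities are clamped at 1e-12 before logs; z-score
standard deviations floor at 1e-8 (with constant dimensions zeroed as
above); orthogonality of rotations is enforced to 1e-8. All randomness
flows from explicit integer seeds through `numpy` SeedSequence spawning, so
identical configurations reproduce losses and embeddings byte-for-byte.

## Known limitations

* The sequence branch's offline embedder is intentionally simple; plugging
  in a frozen language model changes the absolute quality of fused
  representations but not the pipeline mechanics.
* Rotation invariance of the fused vector is exact for the sequence and
  graph branches only; the cloud branch is robust only to the extent the
  augmentation-trained autoencoder makes it so, and the residual drift is
  reported rather than bounded.
* Trimming clouds to the first M atoms in record order is deterministic
  but biased toward the chain's beginning for very large proteins; use the
  seeded subsample flag when that matters.
* The GCN's 21-dim one-hot features limit how well the inner-product
  decoder can separate structurally similar node pairs on small regular
  graphs; the transductive benchmark reflects what the architecture
  extracts from remnant topology plus residue identity.
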