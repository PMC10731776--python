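# Methods

`microlink` predicts unknown microbe–disease associations from a curated
binary association matrix **A** (rows = microbes, columns = diseases) plus
optional side information (disease ontology DAGs, disease–symptom weights,
microbe–drug associations with a drug–drug similarity). The pipeline has
three stages: multi-view similarity construction with network fusion, node
representation learning with a multi-scale variational graph autoencoder
(VGAE) regularized by a 2-Wasserstein prior, and gradient-boosted pair
classification under cross-validation.

## Similarity networks

**Disease semantic similarity (DSS1).** Each disease D is equipped with a
rooted ancestor DAG. Every node d in the DAG contributes
C_D(d) = max over root-to-d paths of Ω^depth — the contribution factor Ω
decays per hop away from the disease itself and the most favourable path
counts; C_D(D) = 1. The semantic value V(D) = Σ_d C_D(d), and

    DSS1(D1, D2) = Σ_{d ∈ T(D1) ∩ T(D2)} (C_{D1}(d) + C_{D2}(d)) / (V(D1) + V(D2)).

Ω defaults to 0.5, the convention of the ontology-similarity literature
this construction comes from; it is exposed in `RunConfig.omega`. Because
Ω ≤ 1, the max-over-paths reduces to a BFS shortest-hop computation, which
the tests verify against an exhaustive path-enumeration oracle.

**Disease symptom similarity (DSS2)** is cosine similarity between
nonnegative disease × symptom weight vectors (IDF-style weights in real
data). Diseases with empty symptom vectors get zero similarity
off-diagonal (cosine is undefined there) and a warning, so NaNs never
reach the fusion stage.

**Gaussian interaction-profile kernel (GIP).**
K(i, j) = exp(−η ‖p_i − p_j‖²) over binary interaction profiles (columns
of A for diseases, rows for microbes), with bandwidth
η = η′ / mean_k ‖p_k‖² and η′ = 1.

**Functional similarity (DFS).** Microbes are compared through their
associated disease sets using best-match averaging over a base disease
similarity (DSS1), and analogously through drug sets over a supplied
drug–drug similarity. Two drug-side databases are combined entrywise:
average where both are nonzero, the nonzero entry otherwise. Entities with
empty partner sets get zero similarity off-diagonal, with a warning.

## Similarity network fusion

Per axis, the available views are fused by cross-diffusion. Each view W is
normalized into a status matrix P with P(i,i) = 1/2 and
P(i,j) = W(i,j) / (2 Σ_{k≠i} W(i,k)), and sparsified into a row-stochastic
K-nearest-neighbour kernel S (ties at the K-th neighbour break by label
order, for bit-reproducibility). The update

    P_v ← normalize( S_v · mean_{u≠v}(P_u) · S_v^T ),   re-symmetrized,

runs for t = 20 iterations (early stop when the largest change drops below
1e-8). The output is the mean of the final status matrices, renormalized
with the identity added back, scaled into [0, 1] with diagonal exactly 1.
The per-iteration renormalization matters: the bare recurrence is a
rank-collapsing random walk whose iterates forget node-specific structure,
while the renormalized diffusion keeps half of each row's mass on the
diagonal throughout, so the fused network stays diagonally dominant and
node identity survives into the encoder. K defaults to 5 on the disease
axis and 30 on the microbe axis.

Duplicate views are collapsed before fusion, and a single (distinct) view
passes through unchanged up to the final [0, 1] rescale: cross-diffusion
needs at least two distinct information sources, and a degenerate view set
should not be distorted by pretending otherwise. This gives the exact
rank-preservation property the fusion tests assert for single-view and
identical-multi-view inputs.

## Multi-scale variational graph autoencoder

Per axis, the fused network SM (entries in [0, 1]) is the weighted
adjacency and the raw association profiles are node features X (rows of A
for microbes, columns for diseases). With
N = D̃^{−1/2} (SM + I) D̃^{−1/2}:

    X̄₁ = ReLU(N X W₀ + b₀)
    X̄₂ = ReLU(N X̄₁ W₁ + b₁)
    μ_i = N X̄₂ W_μ^i + b_μ^i,   log σ_i = N X̄₂ W_σ^i + b_σ^i,   i = 1..M

with parallel variational heads at scales {16, 32, 64}. Reparameterized
samples Z_i = μ_i + σ_i ⊙ ε (ε drawn independently per scale) concatenate
into Z (112 dimensions at the defaults). The main decoder reconstructs the
adjacency as sigmoid(Z Zᵀ); two auxiliary one-hidden-layer MLPs (width
128, ReLU, sigmoid output) reconstruct X̄₁ and X̄₂ from Z ("multi-order
node-embedding reconstruction").

**Loss.** Total = adjacency reconstruction + Wasserstein prior +
½ (aux₁ + aux₂).

* The adjacency term is the canonical graph-autoencoder reconstruction
  objective: class-balanced cross entropy with positive mass reweighted by
  (n² − S)/S and the term rescaled by n²/(2(n² − S)), S = ΣSM. Fused
  networks are sparse (most entries near 0), and without the balancing the
  decoder minimizes risk by idling at sigmoid = 1/2 instead of modelling
  structure.
* The prior term is, per scale, the 2-Wasserstein distance between the
  n-point latent sample cloud and an equal-size standard-normal cloud,
  averaged over scales, computed by log-domain Sinkhorn (ε = 0.1,
  30 iterations during training) with the transport plan held fixed for
  the gradient. A closed-form per-node diagonal-Gaussian W2 is available
  as `wd_mode="gaussian"` and doubles as the test oracle.
* Auxiliary targets are the detached, per-column min-max-normalized hidden
  activations (cross entropy needs [0, 1] targets; ReLU outputs are
  unbounded). Constant columns map to 0.

A property of the empirical-cloud prior worth knowing: in latent dimension
d ≥ 16 the W2 between two independent standard-normal n-point clouds
(≈ √(2d)) exceeds the W2 from a collapsed point mass at the origin to a
prior cloud (≈ √d), so the term is minimized by shrinking the latents —
it behaves as a ridge penalty rather than a distribution matcher, and
training settles into a near-deterministic autoencoder regime (σ → 0)
with shrunken but structured means. The per-node Gaussian mode avoids this
but keeps σ pinned near 1, and the resulting sampling noise swamps the
reconstruction gradient; it performs clearly worse end-to-end, which is
why the cloud mode is the default.

**Optimization.** Full-graph Adam steps with a step-decayed learning rate
(×0.5 every `lr_step` epochs). Gradients are hand-derived reverse-mode
NumPy (the graphs here have at most a few thousand nodes, so dense
full-graph training is fast and dependency-free) and are verified against
central finite differences in the tests. Defaults — learning rate 1e-3,
1200 epochs, lr_step 300 — were chosen from convergence behaviour on
synthetic worlds: Adam at 1e-2 can push the shared ReLU layers into a dead
state from which no gradient recovers (the variance heads then freeze at
σ = 1 and reconstruction stalls permanently), while 1e-3 trains stably;
the variance heads start at 0.1 × Glorot scale so early sampling noise
does not drown the reconstruction signal. Evaluation-mode embeddings are
the concatenated means (no sampling), making downstream features
deterministic. Two independent models are trained, one per axis, sharing
hyperparameters.

## Pair classification and evaluation

Each candidate (microbe, disease) pair is the concatenation of its two
embeddings (224 dims at defaults). All known associations are positives;
an equal number of never-observed cells is drawn uniformly without
replacement (`negative_ratio = 1`, consistent with the near-symmetric
precision/recall the protocol reports). An XGBoost classifier with
library-default parameters is evaluated under stratified tenfold
cross-validation; AUROC and AUPR are threshold-free, F1/precision/recall/
accuracy use a 0.5 decision threshold. Similarities and embeddings are
computed once on the full association matrix before splitting — the
standard protocol for this task family, which means metrics quantify
ranking quality under profile leakage, not prospective generalization.
Candidate ranking for one disease scores all non-associated microbes and
returns the top k (ties broken by label).

## Synthetic study worlds

The generator plants the structure the pipeline assumes: round-robin
cluster labels for microbes and diseases, identity cluster compatibility,
A(i,j) ~ Bernoulli(p_in) for compatible cells and Bernoulli(p_out)
otherwise, then independent cell flips. Defaults (nm=150, nd=30,
4 clusters, p_in=0.3, p_out=0.02, flip 0.01) mirror the aspect ratio and
sparsity of the curated databases (many more microbes than diseases,
~400–450 positives), so the default KNN values remain sensible. The DAG
forest gives each cluster a shared ancestor chain (depth 3) which each
disease joins with probability `share_prob = 0.8` (attaching to the first
two chain nodes, creating diamond-shaped multi-path DAGs); otherwise it
gets a private chain. The symptom matrix is uniform noise plus a
cluster-specific loading template scaled by `signal = 2.0`. Drug data are
two independent microbe × drug planted matrices plus a block-structured
drug similarity. All randomness derives from one seed through
stage-name-keyed substreams.

What the generator does **not** emulate: long-tailed degree distributions,
taxonomy-correlated microbe similarity, database-specific curation biases,
and name-normalization noise. Passing tests therefore demonstrate that the
implementation recovers planted block structure under the stated noise —
not that real-database headline numbers transfer.

## Numerical choices and degenerate inputs

* Sinkhorn runs in the log domain on the dual potentials, so ε as small as
  0.005 is stable; non-convergence within the iteration budget returns the
  current value with a warning. Exact optimal transport between equal-size
  uniform clouds is an assignment problem, solved with the Hungarian
  algorithm for the test oracle.
* Similarity matrices are validated symmetric to 1e-9, exactly
  symmetrized, and clipped to [0, 1]; matrix TSVs are written with 17
  significant digits and re-read with round-trip float parsing, so file
  round-trips are bit-exact.
* All-zero association matrices make the GIP bandwidth undefined and
  raise; all-zero similarity rows fall back to uniform off-diagonal status
  mass with a warning; p_in = p_out is allowed in the generator (the null
  world used by the signal-degradation checks).
* Problem sizes in the test suite are scaled to what the checks need:
  formula oracles run on ≤ 20-node inputs, optimal-transport checks on
  ≤ 64-point matchings plus one 2000-draw cloud comparison, and the
  end-to-end recovery gate on the default 150 × 30 world.

## Known limitations

* The evaluation protocol shares similarity/embedding information across
  CV folds (see above); absolute metric values are protocol-specific. In
  particular, a signal-free world (p_in = p_out) still scores well above
  0.5 because each pair's own label is partially readable from the
  full-matrix profiles inside its embedding; the label-permutation test
  is the leakage-free chance calibration.
* The empirical-cloud Wasserstein prior is a shrinkage penalty in high
  dimension rather than a calibrated distribution match.
* With both pair sides compressed into latent spaces, axis-aligned tree
  splits recover pair identity only approximately; on planted worlds the
  end-to-end AUROC of the full embedded pipeline trails a raw-profile
  baseline by a few points.
* The drug–drug similarity matrix is consumed as given, never recomputed.
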