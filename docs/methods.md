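# Methods

drivnet prioritizes candidate cancer driver genes by combining two signals:
the *functional* signal carried by somatic mutation profiles diffused over a
gene interaction network, and the *structural* signal carried by each gene's
topological role in the resulting mutation integration network. This note
documents the model, the numerical choices, the synthetic study conditions,
and the limits of what the tests demonstrate.

## 1. Network propagation of mutation profiles

For each sample s with binary mutation indicator vector Y over the gene
universe, the profile is smoothed over the interaction network by iterating

    F_t = α · W′ · F_{t−1} + (1 − α) · Y,    F_0 = Y,

where W′ = D^{−1/2} A D^{−1/2} is the symmetrically degree-normalized
adjacency matrix. Because the spectral radius of W′ is at most 1, the map is
a contraction for α < 1 and converges to the unique fixed point
F_∞ = (1 − α)(I − α W′)^{−1} Y; the implementation iterates until
‖F_t − F_{t−1}‖₂ < 10⁻⁶ (configurable `tol`), capped at 10,000 iterations.
Tests verify the iterate against the dense closed-form solve on random
graphs. Entrywise, F need not stay below max(Y) (W′ rows are not
stochastic); what does hold, and is tested, is non-negativity and the L2
bound ‖F‖₂ ≤ ‖Y‖₂.

Parameters: `restart_alpha` (default 0.5) balances diffusion against the
original indicator; `tol` (default 1e-6). Isolated genes keep zero rows in
W′; their fixed-point value is simply (1 − α) · Y at that gene.

## 2. The mutation integration network

Propagated gene profiles (columns of F across samples) are compared
pairwise and thresholded: an edge joins genes x, y iff sim(x, y) > 0.5
(strict, configurable `sim_cutoff`). Genes left without any edge are
dropped before embedding — a random-walk context is undefined for isolated
nodes — and are excluded from classification, with counts logged.

**Choice of similarity (a deliberate design decision).** The default is
**cosine** similarity of the non-negative propagated columns. Pearson
correlation — the other obvious candidate, also available via
`sim_method=pearson`, along with raw `dot` — has a structural defect for
this pipeline: each gene's propagated column is dominated by its own binary
indicator (the (1−α) self-term), so after centering, the correlation
between two genes collapses to approximately the local normalized-adjacency
weight 1/√(d_x d_y), *independent of mutation rates*. A network built that
way encodes only low-degree adjacency, not mutation recurrence, and
recurrently mutated modules never become the dense core the downstream
structural embedding is supposed to recognize. Cosine keeps the mean
(recurrence) component, is bounded in [0, 1] on non-negative profiles — so
the 0.5 cutoff remains meaningful — and makes planted driver modules
recoverable (section 6).

## 3. Structural gene embedding

The integration network is embedded by structural similarity, so genes with
similar topological roles — even in different connected components — get
nearby vectors.

1. **Hop-degree signatures.** For each gene x and hop k, s(R_k(x)) is the
   sorted degree sequence of nodes at exactly distance k (exact BFS).
2. **Distances.** f_k(x,y) accumulates, over layers 0..k, the exact DTW
   alignment cost of the two sequences under the element cost
   max(u,v)/min(u,v) − 1. Degrees are shifted by +1 before the ratio so
   degree-0 entries cannot divide by zero. A pair stops accruing layers once
   either hop set becomes empty. By default all pairs are compared
   (`distance_mode=global`), including cross-component pairs;
   `component` mode restricts to within-component pairs as an optimization.
3. **Multilayer graph.** Layer k connects x, y with weight
   ω_k = e^{−f_k}; a node's copy links upward with weight log(Γ_k(x) + e)
   — Γ_k(x) counting its layer-k edges heavier than the layer mean — and
   downward with weight 1.
4. **Biased walks.** Walks start in layer 0. With probability q (default
   0.7, `stay_prob`) the walk steps within the layer, choosing y with
   probability e^{−f_k(x,y)} / Z_k(x); otherwise it jumps up/down with
   probabilities proportional to the inter-layer weights. Layer changes
   emit no token; recorded tokens are gene identities. Defaults: 20 walks
   per gene, length 80. Every (gene, walk-index) pair draws from its own
   seeded stream, so the corpus is reproducible regardless of iteration
   order.
5. **Skip-gram.** A hierarchical-softmax skip-gram (Huffman tree over token
   frequencies, window 10, 5 epochs, initial learning rate 0.025 with
   linear decay, min count 0) trains single-threaded with its own PRNG, so
   embeddings are bit-reproducible for a seed. Default dimension 128.
   Hierarchical softmax was chosen over negative sampling deliberately:
   with frequency-weighted noise sampling, small walk corpora collapse
   toward a dominant direction (median random-pair cosine ≈ 0.6 on the
   twins fixture) and structural equivalence is lost in co-occurrence
   noise; under hierarchical softmax the space stays spread (median
   random-pair cosine ≈ 0.05) and exact structural twins separate cleanly.

k\* (the number of layers) defaults to the graph diameter capped at 6
(`k_max`); the cap bounds the quadratic pairwise cost on large sparse
graphs. Exact-diameter behaviour is available by raising the cap.

## 4. Classification and ranking

Each embedded gene is one observation (its embedding vector); label 1 iff
the gene is in the benchmark driver set, every other embedded gene counted
as negative (unlabeled-as-negative; no curated negative set exists). Five
model families are supported: k-nearest neighbours, logistic regression,
SVM, random forest, and XGBoost gradient-boosted trees (regularized
objective with leaf-count penalty γ and squared-leaf-weight penalty λ);
hyperparameters are library defaults, recorded per run.

Class imbalance is handled by undersampling: the majority class is
subsampled without replacement to the minority size. Evaluation repeats
10 balanced draws × 10 stratified 80/20 holdout splits = 100 runs; the
reported value is the arithmetic mean of per-run metrics (accuracy,
precision, recall, specificity, F1, ROC-AUC), with standard deviations.
Stratification prevents single-class test folds on small positive sets; a
degenerate fold would be redrawn with the next seed and logged. The final
ranking trains on one balanced draw and scores every embedded gene by its
positive-class probability; ties break lexicographically, so storage order
never affects the list. A consensus utility intersects the top-n of several
models' lists minus the benchmark, ordered by mean rank.

Metrics are computed from explicit confusion counts; zero-denominator
metrics report 0 and are flagged rather than raising, keeping 100-run
averages well-defined. ROC curves collapse tied scores into single
vertices, so the trapezoid AUC equals the tie-aware Mann–Whitney statistic
(tests verify this against a brute-force pairwise count). A
precision–recall trapezoid (`average_precision`) is provided alongside.

## 5. Seeds and determinism

One master seed deterministically derives labeled substreams (BLAKE2 hash
of `"{seed}:{label}"`, reduced mod 2³¹) for walks, evaluation and ranking.
With a single worker, two runs of the same configuration produce identical
ranked lists; this is enforced by tests. Note that the walk streams are
indexed by each gene's rank in sorted order, so determinism under renaming
holds for order-preserving relabelings (this is what the label-invariance
test checks); an order-scrambling rename reseeds the walks.

## 6. Synthetic study conditions

`make_scale_free` draws a preferential-attachment network (default
attachment 2, average degree ≈ 4, matching the sparsity of curated
protein-interaction networks at desk scale). `simulate_cohort` plants
`n_drivers` genes mutating i.i.d. at `p_driver` per sample against a
passenger rate `p_passenger`; drivers form a connected BFS-grown module by
default, because the framework's premise is that diffusion amplifies
functionally clustered signal (`driver_placement=random` is the hard-mode
control). The default recovery conditions are 300 genes, 120 samples, 25
module drivers, p_driver 0.25, p_passenger 0.03 — sized so the full
pipeline runs in well under a minute while leaving the positive class small
and imbalanced (≈ 10%), as in real benchmarks.

`make_structural_twins` builds two disjoint isomorphic copies of a 10-node
threshold graph (vertices added alternately dominating/isolated) plus a
15-node sparse random component. The threshold template is essentially
asymmetric — degrees pairwise distinct up to one tie — so the returned
counterpart pairs are, by construction, the structurally identical pairs of
the fixture, and its degree range (up to 9) exceeds the random component's,
leaving template nodes no near-equivalents elsewhere. A symmetric template
(say, mirrored barbells) would defeat the fixture's purpose: its internal
automorphism classes would make many "random" pairs exactly equivalent,
and tests of counterpart similarity would measure fixture confounds rather
than embedding quality.

What the synthetic conditions do **not** emulate: mutational signatures,
copy-number events, per-gene background mutation rates, hypermutated
samples, network noise (false interactions), or gene-length effects.
Passing the recovery test therefore shows the machinery is sound — signal
planted as the model assumes is found, permuted labels are not — but says
nothing about performance on real cohorts, where label noise and
confounders dominate.

## 7. Known limitations

- All-pairs structural distances cost O(n² · DTW) per layer; the k\* cap
  and the component mode mitigate but do not remove this. The compressed
  degree-sequence approximations of the original structural-embedding
  literature are out of scope.
- The classifier sees only embedding vectors; mutation frequency is not a
  direct feature (it enters via the network). On real data one would
  combine both.
- `sweep_alpha` reruns the entire pipeline per grid point and selects by
  mean precision; at default settings this is minutes of compute.
- Benchmark labels are treated as ground truth; the unlabeled-as-negative
  convention systematically understates precision when genuinely novel
  drivers exist among the negatives — which is the point of the consensus
  ranking utility.
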