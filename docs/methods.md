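# Methods

This note documents the models, the choices that were genuinely open, the
synthetic benchmark's scope, and the numerical conventions, at the level of
detail a maintainer or reviewer needs to re-derive the behavior.

## Model

### Conjoint-triad sequence features

The 20 standard amino acids are partitioned into 7 physicochemical classes
(by dipole and side-chain volume): {A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W},
{R,K}, {D,E}, {C}. A length-3 window slides along the sequence; each window
whose residues are all standard contributes one count to the class triple
(c₁,c₂,c₃) at flat index c₁·49 + c₂·7 + c₃. Counts are divided by the number
of valid windows, so the 343-vector is a frequency distribution and is
length-independent. Windows containing non-standard letters (B, J, O, U, X,
Z) are skipped rather than remapped — no chemistry is invented. Sequences
shorter than 3, or with no valid window, produce the zero vector with a
logged warning; an exception would make batch encoding of real proteomes
(which contain fragments) unusable. The class table is loadable from a
plain-text file so an alternative partition can be swapped in.

### Hypergraph

Hyperedges are the **maximal cliques** of the PPI network with at least
`min_size = 3` members. A clique is the strongest topological signature of
an all-to-all interacting unit, and maximal-clique enumeration
(networkx's Bron–Kerbosch) is deterministic and reproducible, unlike
percolation-style clique merging, which adds a resolution parameter. Nodes
covered by no clique receive a singleton hyperedge so that every vertex
degree is positive and the normalized operator exists. Hyperedge weights
default to 1; the weight matrix is kept in the data model because the
propagation operator includes it.

The smoothing operator is
`A = D_v^{-1/2} H W D_e^{-1} H^T D_v^{-1/2}`
with D_v the weighted vertex hyperdegrees and D_e the hyperedge
cardinalities. With W = I this is a symmetrized hypergraph random walk:
spectral radius exactly 1, with eigenvector D_v^{1/2}·1 — both asserted in
the test suite on random hypergraphs, which pins the normalization to the
correct sides.

### HGVAE

Encoder: two hypergraph convolutions. Layer one is ReLU(A X Θ₁) with
hidden width 256; layer two forks into two linear heads producing μ and
log σ² per node (the final layer omits the ReLU so the Gaussian parameters
are unconstrained). The log-variance parameterization is used for
numerical stability. Latent dimension defaults to 100, matching the
complex-embedding dimension downstream.

Decoder: for each hyperedge, member latents are scored by a two-layer
LeakyReLU projection (width 64, slope 0.01) giving one scalar per member;
the softmax of these scores over the members is the attention weight
vector, and the hyperedge embedding is LeakyReLU of the attention-weighted
sum of member latents. The incidence matrix is reconstructed entrywise as
sigmoid(zᵢ·eₖ).

Loss: binary cross-entropy of the reconstruction (mean over all |V|·|E|
entries) plus the closed-form KL of the posterior against N(0, I)
(averaged over nodes). Because H is sparse, an unweighted reconstruction
collapses to all-zeros; the positive class is therefore weighted by
(#zeros/#ones) of the target by default (switchable off). One
reparameterized sample of z is drawn per epoch for the reconstruction
expectation; the canonical downstream embedding is μ, so inference is
deterministic.

Optimization: full-batch Adam, learning rate 1e-3, 200 epochs by default.
All randomness (initialization, ε draws, dropout masks) flows through one
seeded NumPy generator, so training is bitwise reproducible. The entire
forward/backward pass is hand-written NumPy; gradients of every parameter
are checked against central finite differences in the test suite
(tolerance ~1e-5 absolute on O(1) gradients), for all three decoder/
propagation modes.

Ablation modes share this code path: `feature_mode="onehot"` replaces X by
the identity (topology only); `propagation="identity"` removes network
smoothing (sequence only); `propagation="gcn"` plus `decoder="adjacency"`
is a conventional pairwise variational graph autoencoder that reconstructs
the self-looped adjacency with sigmoid(zᵢ·zⱼ).

### Complex classifier

A candidate complex is embedded as the column-wise **average** of its
member embeddings. (Averaging, not concatenation: it is the only pooling
that gives a fixed input dimension for arbitrary complex sizes, which a
fixed feed-forward network requires.) The network has four weight layers
(100 → 64 → 32 → 16 → 1) with batch normalization and dropout (rate 0.1)
between the hidden layers and a terminal sigmoid, trained with minibatch
Adam (batch 32, 200 epochs) on binary cross-entropy.

**Input standardization.** The classifier z-scores its inputs on training
statistics stored with the model. HGVAE posterior means can have very
small scale (std ~0.01 on desk-scale benchmarks); feeding them raw makes
the first batch-norm layer operate on variances of order 1e-5, where the
mismatch between per-batch statistics (training) and running statistics
(inference) destroys the decision function even when training loss is low.
Standardization removes the pathology; it changes nothing when inputs are
already O(1).

Negatives are random node sets: sizes resampled with replacement from the
empirical positive size distribution (preserving its power-law shape),
members uniform without replacement, any set identical to a positive
redrawn, at a 5:1 negative:positive ratio. Classifier quality is reported
as AUROC/AUPRC, with mean ± standard error over repeated fresh negative
draws (default 30), plus an optional 5-fold cross-validation mode.

### Mining (seed–expand–merge)

Each PPI edge seeds one candidate. The candidate's admission pool is the
**neighborhood of the seed edge, collected once**; every round, each
remaining pool node is tentatively added, the grown set is scored by the
classifier, and the best-scoring addition is adopted if its score exceeds
α (default 0.9; ties broken to the lexicographically smallest id). Adopted
nodes leave the pool and the pool is never re-expanded.

The fixed pool is load-bearing. If the pool is instead recomputed from the
grown set after every adoption, expansion can leak across complex
boundaries one hop at a time: a trained classifier saturates above α on
"complex plus a few outsiders" sets (they are far from the random-set
negatives it was trained against), and candidates then snowball into
multi-complex chimeras — on the planted benchmark this alone costs
~0.3 F1. Confining a candidate to its seed's neighborhood bounds each
candidate by local topology rather than by classifier calibration.

Merging: candidates are deduplicated as sets, sorted by score (descending,
then size, then members, for determinism); scanning down, a lower-scoring
candidate whose overlap with a retained one exceeds β (default 0.5) is
merged into it when the union outscores the retained candidate and removed
otherwise. Overlap defaults to the NA score (the package's only set-overlap
statistic), with Jaccard as an alternative. Only sets with ≥ 3 members are
reported. Merging is idempotent, which the tests assert.

### Evaluation

NA(p,b) = |p∩b|²/(|p|·|b|); a predicted complex is matched if some
reference complex reaches NA ≥ 0.25 (and symmetrically), giving
precision = N_cp/|P|, recall = N_cb/|B|, F1 their harmonic mean. From
Tᵢⱼ = |bᵢ∩pⱼ|: Sn = Σᵢ maxⱼ Tᵢⱼ / Σᵢ|bᵢ|, PPV = Σⱼ maxᵢ Tᵢⱼ / ΣᵢⱼTᵢⱼ,
Acc = √(Sn·PPV). A predicted complex intersecting nothing contributes zero
to both PPV sums; when the whole T matrix is zero the PPV (and Acc) are
reported as 0 with a warning rather than 0/0.

Biological-property statistics are generic operators: mean pairwise score
over member pairs with a pluggable pair scorer (GO semantic similarity
itself is out of scope — callers supply a pair-score table); per-complex
mean/median/min pairwise Manhattan distance over abundance profiles;
upper-tail hypergeometric enrichment p-values (scipy's survival function;
an exhaustive-summation oracle cross-checks it to 1e-9 in the tests); and
size-matched random pseudo-complexes plus a Wilcoxon rank-sum helper for
null comparisons.

## Synthetic benchmark

`generate_benchmark` emulates the statistical shape of the training data,
not any specific organism:

* complex sizes: discrete truncated power law P(s) ∝ s^(-2) on [3, 20]
  (gold-standard complex catalogues are power-law-like; the exponent is a
  free parameter);
* membership: disjoint by default (overlap optional) so oracle tests can
  assert exact recovery;
* topology: within-complex pairs wired with probability 1.0 by default,
  background pairs at 0.01 — planted complexes are cliques on a sparse
  random background;
* sequences: each complex owns a Dirichlet-random 7-class residue profile;
  members draw each residue from that profile with probability
  `sequence_signal` (0.8 default) and uniformly otherwise — this plants a
  CT-feature signal without any biological claim;
* abundance: members scatter (σ = 0.3) around a shared per-complex latent
  profile over 10 samples, giving within-complex expression concordance.

What passing tests on this generator do **not** show: robustness to the
degree heterogeneity, overlapping membership, and annotation noise of real
PPI datasets; discrimination when sequences carry no compositional signal;
or behavior on complexes with sparse internal connectivity (within-complex
density < 1 weakens the clique hyperedges the encoder relies on). The
noise utility (`perturb_network`) probes false-positive/false-negative
interaction noise only.

Study configuration used by `scripts/acceptance.py` and the end-to-end
tests: 300 nodes, 20 planted complexes for the oracle-recovery experiment
and 30 for the learned runs, background density 0.01, within-complex
density 1.0, sequence signal 0.9, default model configurations, three
seeds for the learned experiment. These sizes keep a full run around a
minute on one CPU while leaving ~1300 edges and ~150 hyperedges — enough
structure for the hypergraph encoder to be non-trivial.

## Numerical conventions and degenerate inputs

* Reconstruction probabilities are clamped to [1e-7, 1 − 1e-7] inside the
  loss; classifier probabilities to [1e-12, 1 − 1e-12].
* Batch norm: eps 1e-5, running-statistics momentum 0.9; minibatches of
  size 1 are skipped (batch statistics undefined).
* Hyperedge order is canonical (sorted member tuples); node order defines
  all matrix row orders; candidate sorting is (score desc, size desc,
  lexicographic members). All ties everywhere break lexicographically.
* Zero-degree vertices are impossible by construction (coverage
  singletons); `propagation_operator` still checks and raises.
* Empty networks yield empty predictions; empty complex sets are rejected
  by the matching metrics (the ratios are undefined).
* Non-finite training loss aborts with a diagnostic rather than continuing.

## Known limitations

* Full-batch dense training: the |V|×|E| reconstruction and |V|×|V|
  operator are dense, appropriate up to ~10⁴ nodes, not proteome-scale
  sparse pipelines.
* The classifier is only calibrated against random node sets; its scores
  on near-complex sets (one subunit short, one intruder added) are
  extrapolations. The fixed-pool expansion rule compensates during mining,
  but the probability values themselves should not be over-interpreted.
* α and β defaults (0.9, 0.5) are conventions, not fitted values; real
  deployments should sweep them against a held-out reference catalogue.
* Identifier namespaces are opaque: no mapping between UniProt accessions
  and systematic names is attempted.
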