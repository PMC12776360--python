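# Methods

## Model

The predictor treats DTI as binary classification over (drug, protein)
pairs, with a representation learner that couples the two modalities.

**Similarity graphs.** Within each modality, entities are nodes and an
edge joins i and k when the Euclidean distance between their embeddings
satisfies S(i,k) ≤ τ (ties included, per the set definition; self-loops
excluded). Because absolute Euclidean thresholds depend on the provenance
and scale of the embeddings, τ defaults to the 10th percentile of the
off-diagonal distance distribution, resolved per modality per dataset; an
absolute threshold and optional row L2-normalization are configuration
switches. Graphs are built over the whole split's entity universe by
default; probes can rebuild them over restricted batch contexts.

**Cross-neighborhood selection (CNS).** At each layer, each protein's
policy over drug candidates is produced by (a) a 2-layer GCN
(symmetrically normalized adjacency with self-loops) over the drug graph,
giving context vectors for every drug, and (b) a pairwise scorer
tanh(qU + cV + b)·W_out emitting two logits per (query, candidate),
softmax-normalized to a strictly positive select/not-select distribution.
The drug-side policy is symmetric over the protein graph. Policies are
separate per layer by default (a flag shares them), and selections are
re-sampled freshly at every layer of every forward pass.

**Straight-through Gumbel-softmax.** Selection bits are sampled by
perturbing log-probabilities with Gumbel(0,1) noise, dividing by the
temperature T, and softmaxing; the forward value is the hard argmax bit
while gradients follow the soft relaxation. Probabilities are floored at
1e-10 before the log. A consequence of the 2-way case worth stating: the
hard select *frequency* equals ρ_select at every temperature (argmax is
invariant to the positive scaling by 1/T), so the quantity that T
actually controls is the expected soft selection mass, which flattens
toward 0.5 as T grows. The temperature sweep reports both measures.
Evaluation mode replaces sampling with the deterministic policy argmax, so
inference is reproducible and the batch-stability probe measures only
graph-context sensitivity.

**Attention updates.** Per layer and head, intra-graph coefficients are a
softmax over LeakyReLU(φᵀ[Wp_i ‖ Wp_k]) (negative slope 0.2, the
GAT-family convention) across the node's graph neighbors, and cross-graph
coefficients are the analogue over the selected cross-modal set. The
update σ(Σ α W₁ p_r + Σ β W₂ d_r) uses σ = ELU, and head outputs are
averaged. The updating node is included in its own intra-neighborhood by
default (flag to disable): without a self term, isolated nodes would lose
their identity entirely. Empty neighbor sets contribute a zero vector —
a softmax is never taken over an empty set. The cross coefficients in the
drug update attend from the drug to its selected proteins, i.e. the
construction is symmetric in the two sides.

**Width alignment.** Protein and drug encodings generally have different
widths (p ≠ q), while cross attention applies one W_cr to both sides, so
learnable linear projections map X and Y to a shared width d before layer
one. The residual fusion Z = [(p_i + δ·x̃_i) ‖ (d_j + γ·ỹ_j)] uses
separate learned projections x̃, ỹ of the *raw* initial encodings to width
d, so Z ∈ R^{2d}.

**Objectives.** The MLP head (two hidden ReLU layers by default, sigmoid
output) is trained with mean binary cross-entropy (logs clamped at 1e-12).
The supervised contrastive term treats, for each anchor pair k, the other
same-label batch members as positives P(k) against all other batch
members A(k), averaging −(1/|P(k)|) Σ log softmax similarities; anchors
with no same-label partner are skipped (the expression is undefined at
|P(k)| = 0). Similarity defaults to cosine scaled by 1/τ_c — the NT-Xent
convention; raw dot products grow with embedding norm and destabilize the
softmax — with a dot-product flag for the literal inner-product form.
Total loss: L_BCE + λ·L_contrastive.

## Defaults that matter

| parameter | default | meaning |
|---|---|---|
| `hidden_dim` d | 32 | shared node width after input projection |
| `n_layers` | 2 | selection + attention layers |
| `n_heads` H | 2 | attention heads, outputs averaged |
| `temperature` T | 1.0 | Gumbel-softmax sharpness |
| `threshold_percentile` | 10 | graph density per modality |
| `delta`, `gamma` | 1.0 | residual scales in pair fusion |
| `lam` λ | 0.1 | contrastive weight |
| `tau_c` | 0.5 | contrastive temperature |
| `learning_rate` | 1e-3 | Adam |
| `batch_size` | 128 | pairs per gradient step |
| `max_epochs` / `patience` | 200 / 20 | early stop on validation AUROC |

Early stopping monitors validation AUROC with ties broken by validation
BCE: with very small validation sets the AUROC saturates immediately and a
pure-AUROC patience would freeze a barely trained snapshot. Training
aborts and restores the last finite parameters if the loss goes
non-finite. Rankings for EF/BEDROC break score ties by stable sort on
(−score, original index); EF cutoffs use k = ceil(pct/100 · N); split
sizes use floor for the validation and test shares with the remainder to
train. All randomness flows through `numpy.random.default_rng` (PCG64)
generators derived from explicit seeds, so fits, splits and synthetic
data are bit-reproducible.

## Evaluation protocol

Warm splits partition interaction pairs; cold-drug / cold-protein splits
partition the cold-side *entities* at the (0.79, 0.01, 0.20) ratios, with
pairs inheriting their entity's partition, so train and test entity sets
are disjoint by construction. Negatives are sampled uniformly from pairs
not in the positive set, restricted to the partition's allowed entities,
at `negative_ratio` per positive (1 = balanced, 10 = unbalanced), capped
at the available pool. Repeated runs use seeds seed+0..n−1 and report
means. AUROC/AUPRC come from scikit-learn; EF and BEDROC (Truchon–Bayly,
α = 80.5) are implemented directly and cross-checked against rdkit's
reference implementations in the test suite.

## Synthetic data

The generator plants the statistical structure the model's premises
require. K cluster centers in an 8-dimensional latent space generate
protein latents u_i and drug latents v_j (within-cluster spread 0.25);
observed embeddings are fixed random linear images plus Gaussian
observation noise (σ = 0.1), which makes within-modality similarity
graphs genuinely homophilous. A pair interacts with probability
sigmoid(c·⟨u_i, v_j⟩ + b), c = 3.0, with b solved by bisection so the
expected prevalence hits `positive_rate`; only sampled positive pairs are
emitted, mirroring real DTI tables where non-interactions are unobserved.
The frozen test fixture uses m=40, n=60, p=q=16, K=4, prevalence 0.15,
seed 1234.

Regimes:

- **separable** — the defaults above; the Bayes-optimal ranking computable
  from the latent truth is essentially perfect, so a correctly wired model
  should approach AUROC 1 on a warm split.
- **null** — positive pairs reassigned uniformly at random (same count);
  any test AUROC materially away from 0.5 would indicate leakage.
- **noisy_cross_modality** — drug-side observation noise inflated 20×, so
  raw drug encodings (and the drug graph built from them) are largely
  swamped while the latent signal is intact. This is the regime for the
  variant comparison, run at prevalence 0.06: with scarce supervision and
  a corrupted modality, attending indiscriminately to all cross-modal
  candidates injects noise, and learned selection is what separates the
  full model from its reduced variants. The regime was calibrated so the
  task sits in the assay's dynamic range — at mild noise or plentiful
  supervision even an embedding-only MLP saturates the task and the
  comparison measures nothing.

What passing on this generator does and does not show: it demonstrates
that every mechanism is wired correctly (gradients reach the policies,
selection responds to temperature, attention normalizes, splits do not
leak) and that the model exploits planted cross-modal homophily. It does
not show performance on real chemistry: real embeddings are not linear
images of a shared latent space, real negatives are unverified rather
than known absent, and cold-start difficulty here is milder than with
scaffold- or homology-confounded data.

## Ablation and diagnostics protocol

The variant comparison trains full, select-all ("without dynamic
neighborhood", actions ≡ 1) and no-stack (projected embeddings straight to
fusion and head) models over 10 seeds (fresh dataset draw, split and
initialization per seed; max 60 epochs, patience 15) and compares
per-seed test AUROC with a one-sided rank-sum test. At these problem
sizes the mean ordering (full ≥ select-all, full ≥ no-stack) is the
reproducible signal; the rank-sum p-value is reported but typically not
significant with n = 10 overlapping seed distributions. The noise probe
perturbs only the neighbor (key/value) path with seeded Gaussian noise,
leaving the query path clean, and records AUROC per σ. The
batch-stability probe rebuilds the similarity graphs over 30 random
entity contexts that always contain the anchor pair and reports per-anchor
score dispersion in deterministic-inference mode.

## The autodiff engine

The model needs gradients through masked softmaxes, graph convolutions
and the straight-through estimator. `dcgat.autodiff` is a small
reverse-mode tape over numpy arrays: each op records a backward closure,
and `backward()` walks the graph in reverse topological order. It
implements exactly the ops the model uses (broadcast arithmetic, matmul
including the batched (m,n,h)@(h,k) case, elementwise nonlinearities,
reductions, gather with scatter-add backward, concatenation) plus Adam.
Gradient correctness is property-tested against central finite
differences. It is sized for desk-scale graphs (hundreds of nodes); it
makes no claim to framework-scale performance.

## Known limitations

- Attention and selection are dense (O(m·n) policies per layer); the
  implementation targets hundreds of entities, not 10^5.
- No temperature annealing, edge features, sparse kernels, or alternative
  similarity kernels (cosine/RBF graphs, kNN graphs).
- Cold splits are entity-disjoint but not homology- or scaffold-aware, so
  similarity leakage across splits is possible with real data.
- The validation share of the default ratios (1%) is tiny; early stopping
  therefore leans on the BCE tie-break and small-validation noise remains.
- Pretrained-encoder adapters are interface-only; the built-in hash
  encoder is a deterministic stand-in, not a learned representation.
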