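# Methods

## Model and assumptions

The classifier treats each omics data type as an independent *source of
evidence* about a sample's class. Three assumptions drive the design:

1. **Samples that are similar within one omics tend to share a class.**
   Similarity is measured by the cosine of the angle between feature
   vectors, which is scale-free — appropriate after per-column [0,1]
   scaling, where absolute magnitudes are not comparable across
   features. A Euclidean-distance variant is kept for controlled
   comparison.
2. **Neighbourhoods are higher-order, not pairwise.** One hyperedge per
   sample containing its k nearest neighbours (self included) encodes a
   group relation; the convolution operand
   L_h = D_v^{−1/2} G D_e^{−1} G^T D_v^{−1/2} averages features over
   shared hyperedges. Since all hyperedges have exactly k members,
   D_v^{−1} G D_e^{−1} G^T is row-stochastic, hence L_h is symmetric
   PSD with eigenvalues in [0, 1]; it is used directly as a smoothing
   operator (not as I − operator), and no hyperedge weight matrix is
   used — all hyperedges carry weight 1.
3. **Omics disagree, and the disagreement is informative.** Each
   network outputs non-negative evidence rather than logits; evidence
   defines a Dirichlet opinion whose scalar uncertainty u = b/S falls
   as total evidence grows. Fusion uses the reduced Dempster–Shafer
   rule, whose neutral element is the vacuous opinion — a source that
   has learned nothing contributes nothing, which is what makes the
   fusion "trusted".

Training is transductive: the hypergraph is built once over all
samples (train and test), and the loss is evaluated on training indices
only. This is the standard semi-supervised node-classification setting;
it implies test *features* (never labels) influence the structure, so
reported test metrics are transductive metrics. Per-fold preprocessing
(variance filter, ANOVA-F selection, scaling) is nonetheless fitted on
training rows only, so feature selection never sees test labels.

## Formal pieces

- Opinion map: α = F + 1, p_ij = f_ij/S_i, u_i = b/S_i, S_i = Σ_j α_ij,
  giving Σ_j p_ij + u_i = 1 identically.
- Combination (per sample, two sources): conflict C = Σ_{i≠j} p¹_i p²_j;
  p_k = (p¹_k u² + p²_k u¹ + p¹_k p²_k)/(1−C); u = u¹u²/(1−C). Folded
  left to right over the omics list; the rule is commutative, so the
  order only matters through floating-point round-off.
- Fused Dirichlet recovery: f_ij = b·p_ij/u_i, α_ij = f_ij + 1. The
  factor is the **class count b**: this is the unique choice that makes
  evidence → opinion → recovery the exact identity (verified to 1e−8 in
  the tests), since u = b/S and p = f/S jointly imply f = b·p/u.
- Loss, per opinion: expected cross-entropy under the Dirichlet,
  Σ_j y_ij (ψ(S_i) − ψ(α_ij)), plus λ·KL(Dir(α̃)‖Dir(1)) with
  α̃ = y + (1−y)⊙α, λ = min(1, epoch/annealing_step). The linear ramp
  keeps early training from suppressing evidence before any has been
  accumulated; the λ formula is the ramp normalized into (0,1], i.e.
  the annealing step counts epochs until full penalty weight. Means are
  taken over (masked) samples everywhere, so loss scale is independent
  of cohort size. The total objective sums the fused-opinion term and
  every per-omics term.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `k_neighbors` | 10 | hyperedge size; ~3% of a 300-sample cohort balances smoothing vs locality |
| `hidden_dims` | (64, 32) | two convolution layers; small because post-selection omics blocks are low-dimensional |
| `evidence_activation` | softplus | smooth non-negative head so α = F+1 ≥ 1 with usable gradients (relu/exp selectable) |
| `leaky_slope` | 0.01 | LeakyReLU negative slope |
| `learning_rate` | 1e−3 | Adam step size |
| `weight_decay` | 1e−4 | coupled L2 on all weights |
| `epochs` | 500 | full-batch epochs; well-separated synthetic data converges in ≤150 |
| `annealing_step` | 50 | epochs until the wrong-evidence penalty reaches weight 1 |
| `test_fraction` | 0.2 | holdout fraction, matching the 5-fold CV ratio |

All randomness (fold splits, weight init, noise draws, permutation
importance) fans out from a single integer seed via
`spawn_seeds`, so identical config + seed reproduces a run bit for bit.

## Synthetic data: what it emulates and what it does not

The generator draws class-conditional Gaussians: per omics block, a
random subset of columns (fraction `informative_fraction`, default 0.1)
receives class-specific mean shifts drawn with SD
`effect_size × noise_sd`; all other columns are N(0, noise_sd²) noise.
Defaults — 300 samples, 3 balanced classes, blocks of 120/100/80
features — mirror the shape of mRNA/methylation/miRNA panels after
feature selection at desk scale. Three layouts:

- **redundant** — every omics carries all class contrasts;
- **complementary** — omics o resolves only class o mod b (the other
  classes share a mean pattern in that block), so single-omics accuracy
  is capped near a one-vs-rest ceiling while fusion can be perfect;
- **one_noisy** — the last omics carries no signal, probing whether the
  fusion discounts a worthless source.

The generator does *not* emulate methylation beta-value distributions,
count overdispersion, feature–feature correlation, batch effects, or
class imbalance beyond what `class_proportions` sets. Passing tests on
this data therefore demonstrate the mechanics of the method —
structure building, evidence fusion, uncertainty behaviour, leakage-free
evaluation — not clinical-grade performance on real cohorts.

## Numerical choices

- Zero-norm feature rows get cosine similarity 0 to all others and 1 to
  themselves, so KNN selection stays defined and NaN never enters L_h.
- KNN ties break toward the lower sample index; ANOVA-F ties toward the
  lower column index; argmax prediction ties toward the lower class
  index. All deterministic.
- A perfectly separating column has infinite F statistic and ranks
  first; a constant column has undefined F and ranks last.
- Min-max scaling maps constant columns to 0; scaler parameters are
  frozen at fit time, so held-out extremes map outside [0, 1] rather
  than rescaling the fit.
- DS combination raises `ConflictError` when 1−C ≤ 1e−12 instead of
  renormalizing: silent division blow-up would corrupt training
  invisibly. With softplus evidence and α ≥ 1 opinions this is
  unreachable in normal operation.
- Losses use `scipy.special` digamma/log-gamma; their derivatives
  (polygamma) back the autodiff engine, which is float64 throughout and
  checked against central finite differences at 1e−4 relative
  tolerance.
- The non-trusted baseline (`fusion="mean_evidence"`) averages evidence
  across omics for the training loss and reports softmax scores, so the
  comparison isolates the fusion rule, not the loss family.

## Problem sizes used in tests and the acceptance script

Unit tests run on 60–100-sample fixtures with ≤100 epochs. End-to-end
checks use the generator defaults (n = 300, three omics) with
effect size 5 and 150 epochs, which the loss traces show is well past
convergence for that separation; the noise experiment uses
σ ∈ {0, 0.5, 1, 2, 5} with one repeat per seed across five seeds.

## Known limitations

- Transductive only: predicting a genuinely new sample requires
  rebuilding the hypergraph and re-running the forward pass (training
  need not be repeated, but the operator changes with the cohort).
- The hypergraph is static; it is built once from raw (or preprocessed)
  features and never updated during training.
- Full-batch dense n×n operators scale as O(n²) memory — appropriate
  for cohort sizes in the hundreds to low thousands, not for biobank
  scale.
- Permutation importance attributes through a fixed structure: the
  hypergraph is not rebuilt per permuted column, so importance reflects
  the network's use of a feature, not its role in neighbourhood
  formation.
- The wrong-evidence penalty is the standard KL-to-uniform evidential
  term; other complement losses exist and may change early-training
  dynamics, though not the fixed points (zero non-target evidence).
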