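# trustomics

Trusted multi-omics patient classification with hypergraph convolution
and evidential Dempster–Shafer fusion.

`trustomics` is for researchers who have several sample-aligned omics
matrices (e.g. mRNA expression, DNA methylation, miRNA expression for
the same patients) and integer class labels (disease subtypes, case vs
control), and who want a classifier that (a) exploits higher-order
sample–sample structure within each omics, (b) integrates the omics at
the *evidence* level rather than by concatenating features, and (c)
reports how uncertain it is about each individual patient — so that a
corrupted or uninformative omics degrades confidence instead of
silently corrupting predictions.

## The model

**Per-omics hypergraph.** For each omics, every sample is a vertex and
one hyperedge is centred on each vertex: the vertex plus its k−1
nearest neighbours by cosine similarity. With incidence matrix
G ∈ {0,1}^{n×n}, vertex degrees D_v and hyperedge degrees D_e, the
convolution operand is the normalized hypergraph Laplacian

    L_h = D_v^{−1/2} G D_e^{−1} G^T D_v^{−1/2},

a symmetric smoothing operator with spectrum in [0, 1].

**Evidence extraction.** A per-omics hypergraph convolutional network
stacks layers H^{(l+1)} = LeakyReLU(L_h H^{(l)} Z^{(l)}) (H^{(0)} = X),
then a fully connected layer and a softplus head produce non-negative
evidence F^o ∈ R^{n×b} over the b classes.

**Dirichlet opinions and trusted fusion.** Evidence parameterizes a
Dirichlet, α^o = F^o + 1, read as a subjective-logic opinion with
per-class confidence p_ij = f_ij / S_i and scalar uncertainty
u_i = b / S_i (S_i = Σ_j α_ij), so Σ_j p_ij + u_i = 1. Opinions from
different omics are folded pairwise with the reduced Dempster–Shafer
rule

    C = Σ_{i≠j} p¹_i p²_j,   p_k = (p¹_k u² + p²_k u¹ + p¹_k p²_k)/(1−C),
    u = u¹ u² / (1−C),

and the fused Dirichlet is recovered via f_ij = b·p_ij/u_i. Because an
uncertain source enters the combination close to the vacuous opinion
(u ≈ 1), which is the neutral element, noisy omics are automatically
discounted.

**Training.** Everything is trained end to end (full-batch,
transductive) by minimizing, for the fused opinion and every per-omics
opinion, the Dirichlet-expected cross-entropy
Σ_j y_ij (ψ(S_i) − ψ(α_ij)) plus an annealed KL penalty
KL(Dir(α̃) ‖ Dir(1)) on non-target evidence, with the penalty weight
ramping linearly from 0 to 1 over `annealing_step` epochs.

The networks are small and full-batch, so the package carries its own
compact reverse-mode autodiff engine over numpy arrays
(`trustomics.autodiff`), validated by finite-difference gradient checks
in the test suite.

## Worked example

```python
import numpy as np
from sklearn.model_selection import train_test_split
from trustomics import (RunConfig, SyntheticSpec, cross_validate,
                        generate, predict, train_model)

# three omics blocks, 300 samples, 3 classes, strong redundant signal
dataset, manifest = generate(SyntheticSpec(effect_size=5.0, seed=0))
config = RunConfig(epochs=150, seed=1)
report = cross_validate(dataset, config, n_folds=5)
print("mean:", {k: round(v, 3) for k, v in report.mean.items()})

# complementary split: each omics alone resolves only one class
ds, _ = generate(SyntheticSpec(effect_size=5.0,
                               information_split="complementary", seed=0))
tr, te = train_test_split(np.arange(ds.n_samples), test_size=0.2,
                          stratify=ds.labels, random_state=0)
model = train_model(ds, np.sort(tr), config)
result = predict(model, ds, np.sort(te))
print("fused test ACC:", (result.y_pred == ds.labels[np.sort(te)]).mean())
for name, op in zip(ds.omics_names, result.per_omics):
    print(f"  {name} alone:", (op.P.argmax(1) == ds.labels[np.sort(te)]).mean())
```

Output:

```
mean: {'ACC': 1.0, 'F1_weighted': 1.0, 'F1_macro': 1.0}
fused test ACC: 1.0
  mrna alone: 0.700
  methylation alone: 0.683
  mirna alone: 0.667
```

With strong redundant signal the 5-fold accuracy is perfect. Under the
complementary split no single omics can separate all three classes
(each tops out near the 2/3 ceiling of a one-vs-rest detector), while
the evidence-level fusion recovers the full label structure —
the integration, not any single block, carries the performance.
`result.uncertainty` holds the per-sample fused uncertainty u (here
≈ 0.09 on average), which rises towards 1 as inputs get noisier.

## Command line

```bash
trustomics simulate --out-dir data --effect-size 5 --seed 1
trustomics cv -o mrna=data/mrna.csv -o methylation=data/methylation.csv \
    -o mirna=data/mirna.csv -l data/labels.csv --seed 1 --out report.json
trustomics noise -o ... -l ... --sigmas 0,0.5,1,2,5 --out noise.csv
trustomics importance -o ... -l ... --out importance.csv
```

`preprocess`, `train`, and `evaluate` subcommands cover the
variance-filter → ANOVA-F selection → [0,1] scaling pipeline and single
holdout runs; `--config config.yaml` sets any `RunConfig` field.

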