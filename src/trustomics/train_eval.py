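"""End-to-end training, cross-validation, and the robustness experiments.

One hypergraph + one HGCN per omics, trained transductively (the
structure spans all samples, the loss touches training indices only)
with the evidential loss on the fused and per-omics opinions.  The
evaluation protocol is stratified 5-fold cross-validation reporting
ACC/F1/AUC (binary) or ACC/F1_weighted/F1_macro (multiclass) as
mean +/- std across folds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import evidential, hgcn
from .autodiff import Adam, Tensor
from .evidential import DirichletOpinion, one_hot
from .hypergraph import (build_incidence, cosine_similarity_matrix,
                         euclidean_distance_matrix, hypergraph_laplacian,
                         simple_graph_adjacency_laplacian)
from .io_config import MultiOmicsDataset, RunConfig, spawn_seeds
from .preprocess import Pipeline, PreprocessSpec
from .synthetic import add_gaussian_noise

logger = logging.getLogger("trustomics")

__all__ = ["ExperimentReport", "FittedModel", "PredictionResult",
           "train_model", "predict", "compute_metrics", "cross_validate",
           "noise_experiment", "ablation_run", "feature_importance"]


@dataclass
class ExperimentReport:
    """Per-fold metrics plus their mean and (for >= 2 folds) std."""

    per_fold: list[dict]
    mean: dict
    std: dict | None
    config_snapshot: dict
    seed: int

    @classmethod
    def from_folds(cls, per_fold: list[dict], config: RunConfig
                   ) -> "ExperimentReport":
        if not per_fold:
            raise ValueError("need at least one fold")
        keys = list(per_fold[0])
        mean = {k: float(np.mean([f[k] for f in per_fold])) for k in keys}
        std = ({k: float(np.std([f[k] for f in per_fold], ddof=1)) for k in keys}
               if len(per_fold) >= 2 else None)
        return cls(per_fold=per_fold, mean=mean, std=std,
                   config_snapshot=config.to_dict(), seed=config.seed)


@dataclass
class FittedModel:
    """Per-omics operators and network weights of one training run."""

    config: RunConfig
    operators: list[np.ndarray]        # Lh (or normalized graph adjacency)
    specs: list[hgcn.HGCNSpec]
    params: list[hgcn.HGCNParams]
    train_idx: np.ndarray
    loss_trace: list[float]
    omics_names: list[str]


@dataclass
class PredictionResult:
    y_pred: np.ndarray
    confidence: np.ndarray             # fused P (or softmax scores)
    uncertainty: np.ndarray            # fused u per sample
    per_omics: list[DirichletOpinion]  # source opinions, full sample set


# ---------------------------------------------------------------------------
# operators and fusion


def _build_operator(X: np.ndarray, config: RunConfig) -> np.ndarray:
    if config.similarity == "cosine":
        S, mode = cosine_similarity_matrix(X), "similarity"
    else:
        S, mode = euclidean_distance_matrix(X), "distance"
    if config.structure == "hypergraph":
        return hypergraph_laplacian(build_incidence(S, config.k_neighbors, mode))
    return simple_graph_adjacency_laplacian(S, config.k_neighbors, mode)


def _fused_alpha_t(evidences: list[Tensor], config: RunConfig,
                   n_classes: int) -> Tensor:
    """Differentiable fused Dirichlet parameters under either fusion rule."""
    if config.fusion == "trusted":
        P, U, _ = evidential.opinion_t(evidences[0])
        for F in evidences[1:]:
            P2, U2, _ = evidential.opinion_t(F)
            P, U = evidential.combine_pair_t(P, U, P2, U2)
        return evidential.fuse_alpha_t(P, U, n_classes)
    # mean-of-evidence baseline: no uncertainty weighting
    mean_F = evidences[0]
    for F in evidences[1:]:
        mean_F = mean_F + F
    return mean_F * (1.0 / len(evidences)) + 1.0


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# training / prediction


def train_model(dataset: MultiOmicsDataset, train_idx: np.ndarray,
                config: RunConfig) -> FittedModel:
    """Full-batch transductive training of one HGCN per omics.

    The hypergraphs span every sample; the loss is evaluated on
    ``train_idx`` only.  Deterministic given ``config.seed``.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    if train_idx.size == 0:
        raise ValueError("train_idx must be nonempty")
    train_classes = set(np.unique(dataset.labels[train_idx]).tolist())
    if train_classes != set(range(dataset.n_classes)):
        missing = sorted(set(range(dataset.n_classes)) - train_classes)
        raise ValueError(f"classes {missing} missing from the training split")
    if config.k_neighbors > dataset.n_samples:
        raise ValueError("k_neighbors exceeds the sample count")

    b = dataset.n_classes
    operators = [_build_operator(X, config) for X in dataset.matrices]
    seeds = spawn_seeds(config.seed,
                        [f"init/{name}" for name in dataset.omics_names])
    specs = [hgcn.HGCNSpec(input_dim=X.shape[1], n_classes=b,
                           hidden_dims=config.hidden_dims,
                           leaky_slope=config.leaky_slope,
                           evidence_activation=config.evidence_activation)
             for X in dataset.matrices]
    params = [hgcn.init_params(spec, seeds[f"init/{name}"])
              for spec, name in zip(specs, dataset.omics_names)]

    y = one_hot(dataset.labels, b)
    mask = np.zeros(dataset.n_samples, dtype=bool)
    mask[train_idx] = True
    optimizer = Adam([p for prm in params for p in prm.all()],
                     lr=config.learning_rate,
                     weight_decay=config.weight_decay)
    X_t = [Tensor(X) for X in dataset.matrices]
    L_t = [Tensor(L) for L in operators]

    trace: list[float] = []
    for epoch in range(config.epochs):
        evidences = [hgcn.forward_t(X_t[o], L_t[o], specs[o], params[o])
                     for o in range(dataset.n_omics)]
        alphas = [F + 1.0 for F in evidences]
        fused_alpha = _fused_alpha_t(evidences, config, b)
        loss = evidential.overall_loss_t(alphas, fused_alpha, y, mask,
                                         epoch, config.annealing_step)
        value = loss.item()
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        trace.append(value)
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()

    logger.info("trained %d omics networks for %d epochs, final loss %.4f",
                dataset.n_omics, config.epochs, trace[-1])
    return FittedModel(config=config, operators=operators, specs=specs,
                       params=params, train_idx=train_idx, loss_trace=trace,
                       omics_names=list(dataset.omics_names))


def _forward_evidence(model: FittedModel, matrices: list[np.ndarray]
                      ) -> list[np.ndarray]:
    return [hgcn.forward_t(X, model.operators[o], model.specs[o],
                           model.params[o]).data
            for o, X in enumerate(matrices)]


def _predict_from_evidence(evidences: list[np.ndarray], config: RunConfig,
                           b: int) -> PredictionResult:
    opinions = [evidential.opinion_from_evidence(F) for F in evidences]
    if config.fusion == "trusted":
        fused = evidential.ds_combine_all(opinions)
        scores, uncertainty = fused.P, fused.U
    else:
        mean_F = np.mean(evidences, axis=0)
        scores = _softmax(mean_F)
        uncertainty = b / (mean_F.sum(axis=1) + b)
    # np.argmax breaks ties toward the lowest class index
    y_pred = np.argmax(scores, axis=1)
    return PredictionResult(y_pred=y_pred, confidence=scores,
                            uncertainty=uncertainty, per_omics=opinions)


def predict(model: FittedModel, dataset: MultiOmicsDataset,
            idx: np.ndarray | None = None) -> PredictionResult:
    """Fused predictions, confidences, and per-sample uncertainty.

    ``idx`` restricts the returned rows (e.g. to the test split); the
    forward pass always runs on the full transductive structure.
    """
    result = _predict_from_evidence(
        _forward_evidence(model, dataset.matrices), model.config,
        dataset.n_classes)
    if idx is None:
        return result
    idx = np.asarray(idx, dtype=int)
    return PredictionResult(
        y_pred=result.y_pred[idx],
        confidence=result.confidence[idx],
        uncertainty=result.uncertainty[idx],
        per_omics=[DirichletOpinion(op.P[idx], op.U[idx], op.alpha[idx],
                                    op.n_classes)
                   for op in result.per_omics])


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    scores: np.ndarray | None = None) -> dict:
    """Binary: ACC, F1, AUC (from the positive-class score); multiclass:
    ACC, F1_weighted, F1_macro."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    n_classes = int(max(y_true.max(), y_pred.max())) + 1
    metrics = {"ACC": float(accuracy_score(y_true, y_pred))}
    if n_classes <= 2:
        metrics["F1"] = float(f1_score(y_true, y_pred, zero_division=0))
        if scores is not None:
            pos = scores[:, 1] if np.ndim(scores) == 2 else np.asarray(scores)
            metrics["AUC"] = float(roc_auc_score(y_true, pos))
    else:
        metrics["F1_weighted"] = float(
            f1_score(y_true, y_pred, average="weighted", zero_division=0))
        metrics["F1_macro"] = float(
            f1_score(y_true, y_pred, average="macro", zero_division=0))
    return metrics


# ---------------------------------------------------------------------------
# cross-validation


def _fold_dataset(dataset: MultiOmicsDataset, train_idx: np.ndarray,
                  preprocess_spec: PreprocessSpec | None) -> MultiOmicsDataset:
    """Apply per-fold preprocessing fitted on training rows only."""
    if preprocess_spec is None:
        return dataset
    matrices = []
    for X in dataset.matrices:
        pipe = Pipeline(preprocess_spec).fit(X[train_idx],
                                             dataset.labels[train_idx])
        matrices.append(pipe.transform(X))
    return MultiOmicsDataset(
        omics_names=list(dataset.omics_names), matrices=matrices,
        labels=dataset.labels.copy(), sample_ids=list(dataset.sample_ids),
        n_classes=dataset.n_classes)


def cv_splits(labels: np.ndarray, seed: int, n_folds: int
              ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold indices; a function of the seed and labels only,
    so ablation variants sharing a seed are compared on identical folds."""
    split_seed = spawn_seeds(seed, ["split"])["split"]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=split_seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def cross_validate(dataset: MultiOmicsDataset, config: RunConfig,
                   n_folds: int = 5,
                   preprocess_spec: PreprocessSpec | None = None
                   ) -> ExperimentReport:
    """Stratified k-fold evaluation; folds and training share one seed."""
    seeds = spawn_seeds(config.seed,
                        ["split"] + [f"fold{i}" for i in range(n_folds)])
    per_fold = []
    for i, (train_idx, test_idx) in enumerate(
            cv_splits(dataset.labels, config.seed, n_folds)):
        fold_ds = _fold_dataset(dataset, train_idx, preprocess_spec)
        model = train_model(fold_ds, train_idx,
                            config.replace(seed=seeds[f"fold{i}"]))
        result = predict(model, fold_ds, test_idx)
        per_fold.append(compute_metrics(dataset.labels[test_idx],
                                        result.y_pred, result.confidence))
        logger.info("fold %d: %s", i, per_fold[-1])
    return ExperimentReport.from_folds(per_fold, config)


# ---------------------------------------------------------------------------
# experiments


def _holdout_split(labels: np.ndarray, test_fraction: float, seed: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(labels.size)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=labels, random_state=seed)
    return np.sort(train_idx), np.sort(test_idx)


def noise_experiment(dataset: MultiOmicsDataset, config: RunConfig,
                     sigmas: list[float], target_omics: int = 0,
                     n_repeats: int = 3) -> pd.DataFrame:
    """Accuracy and mean fused uncertainty versus noise level.

    For each repeat (its own split/seed) and each sigma, N(0, sigma^2)
    noise is added to the target omics before the hypergraph is built,
    a model is trained on a stratified holdout, and test ACC plus mean
    test uncertainty are recorded.  Long-form table: one row per
    (sigma, repeat).
    """
    if 0 not in [float(s) for s in sigmas]:
        raise ValueError("sigmas must include 0 (the unperturbed baseline)")
    rows = []
    for r in range(n_repeats):
        seeds = spawn_seeds(config.seed, [f"rep{r}/split", f"rep{r}/train"]
                            + [f"rep{r}/noise{j}" for j in range(len(sigmas))])
        train_idx, test_idx = _holdout_split(
            dataset.labels, config.test_fraction, seeds[f"rep{r}/split"])
        for j, sigma in enumerate(sigmas):
            noisy = dataset.with_matrix(
                target_omics,
                add_gaussian_noise(dataset.matrices[target_omics], float(sigma),
                                   seeds[f"rep{r}/noise{j}"]))
            model = train_model(noisy, train_idx,
                                config.replace(seed=seeds[f"rep{r}/train"]))
            result = predict(model, noisy, test_idx)
            rows.append({
                "sigma": float(sigma),
                "repeat": r,
                "ACC": float(accuracy_score(dataset.labels[test_idx],
                                            result.y_pred)),
                "mean_uncertainty": float(result.uncertainty.mean()),
            })
            logger.info("noise sigma=%.2f repeat=%d: %s", sigma, r, rows[-1])
    return pd.DataFrame(rows)


_ABLATION_AXES = ("structure", "fusion", "similarity", "k_sweep",
                  "omics_subsets")


def ablation_run(dataset: MultiOmicsDataset, config: RunConfig, axis: str,
                 ks: tuple[int, ...] = (2, 5, 10), n_folds: int = 5,
                 preprocess_spec: PreprocessSpec | None = None
                 ) -> pd.DataFrame:
    """Cross-validate every variant along one ablation axis.

    All variants reuse ``config.seed``, so fold splits are identical
    and the comparison is controlled.  Returns one row per variant
    with mean and std of each metric.
    """
    if axis not in _ABLATION_AXES:
        raise ValueError(f"axis must be one of {_ABLATION_AXES}")
    variants: list[tuple[str, MultiOmicsDataset, RunConfig]] = []
    if axis == "structure":
        variants = [(s, dataset, config.replace(structure=s))
                    for s in ("hypergraph", "graph")]
    elif axis == "fusion":
        variants = [(f, dataset, config.replace(fusion=f))
                    for f in ("trusted", "mean_evidence")]
    elif axis == "similarity":
        variants = [(s, dataset, config.replace(similarity=s))
                    for s in ("cosine", "euclidean")]
    elif axis == "k_sweep":
        variants = [(f"k={k}", dataset, config.replace(k_neighbors=int(k)))
                    for k in ks]
    else:  # omics_subsets
        for r in range(1, dataset.n_omics + 1):
            for subset in itertools.combinations(range(dataset.n_omics), r):
                label = "+".join(dataset.omics_names[i] for i in subset)
                variants.append((label, dataset.select_omics(subset), config))
    rows = []
    for label, ds, cfg in variants:
        report = cross_validate(ds, cfg, n_folds=n_folds,
                                preprocess_spec=preprocess_spec)
        row = {"variant": label}
        for metric, value in report.mean.items():
            row[metric] = value
            if report.std is not None:
                row[f"{metric}_std"] = report.std[metric]
        rows.append(row)
    return pd.DataFrame(rows)


def feature_importance(model: FittedModel, dataset: MultiOmicsDataset,
                       config: RunConfig, n_repeats: int = 5,
                       eval_idx: np.ndarray | None = None) -> pd.DataFrame:
    """Permutation importance of every retained feature through the model.

    Importance of feature f = mean drop in accuracy on ``eval_idx``
    (default: the samples outside the model's training split) when
    column f is permuted across samples; the fitted hypergraphs are
    held fixed.  Ranks are per omics, descending importance, ties
    broken by ascending feature index.
    """
    if eval_idx is None:
        eval_idx = np.setdiff1d(np.arange(dataset.n_samples), model.train_idx)
        if eval_idx.size == 0:
            eval_idx = np.arange(dataset.n_samples)
    eval_idx = np.asarray(eval_idx, dtype=int)
    y_true = dataset.labels[eval_idx]
    baseline_evidence = _forward_evidence(model, dataset.matrices)
    baseline = _predict_from_evidence(baseline_evidence, config,
                                      dataset.n_classes)
    baseline_acc = accuracy_score(y_true, baseline.y_pred[eval_idx])
    rng = np.random.default_rng(
        spawn_seeds(config.seed, ["importance"])["importance"])
    rows = []
    for o, name in enumerate(dataset.omics_names):
        X = dataset.matrices[o]
        for j in range(X.shape[1]):
            drops = []
            for _ in range(n_repeats):
                Xp = X.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                evidence = list(baseline_evidence)
                evidence[o] = hgcn.forward_t(Xp, model.operators[o],
                                             model.specs[o],
                                             model.params[o]).data
                perm = _predict_from_evidence(evidence, config,
                                              dataset.n_classes)
                drops.append(baseline_acc
                             - accuracy_score(y_true, perm.y_pred[eval_idx]))
            rows.append({"omics": name, "feature": j,
                         "importance": float(np.mean(drops))})
    df = pd.DataFrame(rows)
    df["rank"] = (
        df.groupby("omics")["importance"]
        .rank(method="first", ascending=False).astype(int))
    return df.sort_values(["omics", "rank"]).reset_index(drop=True)
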