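"""Per-omics filter/select/scale preprocessing.

Pipeline: drop low-variance columns, keep the top features by one-way
ANOVA F statistic between classes, scale to [0, 1].  Fitting uses
training rows only; the fitted state can then transform held-out rows,
so cross-validation never leaks test data into feature selection or
scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.feature_selection import f_classif

from .io_config import DegenerateInputError

__all__ = ["PreprocessSpec", "variance_filter", "select_features_anova",
           "scale_features", "apply_scaler", "Pipeline"]


@dataclass(frozen=True)
class PreprocessSpec:
    """Configuration for one omics block.

    ``n_selected_features=None`` keeps every column that survives the
    variance filter; ``scale`` is one of minmax / zscore / none.
    """

    variance_threshold: float = 0.0
    n_selected_features: int | None = None
    scale: str = "minmax"

    def __post_init__(self) -> None:
        if self.variance_threshold < 0:
            raise ValueError("variance_threshold must be nonnegative")
        if self.n_selected_features is not None and self.n_selected_features < 1:
            raise ValueError("n_selected_features must be positive")
        if self.scale not in ("minmax", "zscore", "none"):
            raise ValueError(f"unknown scale mode {self.scale!r}")


def variance_filter(matrix: np.ndarray, threshold: float
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Remove columns whose (population) variance is <= threshold.

    Returns the reduced matrix and the kept column indices, in their
    original order.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.size == 0:
        raise DegenerateInputError("empty matrix")
    variances = matrix.var(axis=0)
    kept = np.flatnonzero(variances > threshold)
    if kept.size == 0:
        raise DegenerateInputError(
            f"variance threshold {threshold} removed every column")
    return matrix[:, kept], kept


def select_features_anova(matrix: np.ndarray, labels: np.ndarray,
                          n_selected: int) -> tuple[np.ndarray, np.ndarray]:
    """Keep the ``n_selected`` columns with the largest ANOVA F statistic.

    Ties (and undefined F on constant columns, treated as -inf) break
    toward the lower column index; kept indices are returned sorted
    ascending so column order is preserved.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise DegenerateInputError("ANOVA selection requires >= 2 classes")
    if n_selected > matrix.shape[1]:
        raise ValueError(
            f"n_selected={n_selected} exceeds {matrix.shape[1]} columns")
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat, _ = f_classif(matrix, labels)
    # +inf (zero within-class variance) is a perfectly separating column
    # and must rank first; NaN (constant column) ranks last
    f_stat = np.where(np.isnan(f_stat), -np.inf, f_stat)
    order = np.argsort(-f_stat, kind="stable")  # stable: ties keep lower index
    kept = np.sort(order[:n_selected])
    return matrix[:, kept], kept


def scale_features(matrix: np.ndarray, mode: str = "minmax"
                   ) -> tuple[np.ndarray, dict]:
    """Fit a per-column scaler and apply it; returns (scaled, params).

    minmax maps the fitted column range to [0, 1] (constant columns map
    to 0); zscore centres and standardises (constant columns map to 0).
    The params dict transforms held-out rows via :func:`apply_scaler`.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.size == 0:
        raise DegenerateInputError("empty matrix")
    if mode == "minmax":
        lo = matrix.min(axis=0)
        span = matrix.max(axis=0) - lo
        params = {"mode": mode, "offset": lo,
                  "scale": np.where(span > 0, span, 1.0)}
    elif mode == "zscore":
        sd = matrix.std(axis=0)
        params = {"mode": mode, "offset": matrix.mean(axis=0),
                  "scale": np.where(sd > 0, sd, 1.0)}
    elif mode == "none":
        params = {"mode": mode,
                  "offset": np.zeros(matrix.shape[1]),
                  "scale": np.ones(matrix.shape[1])}
    else:
        raise ValueError(f"unknown scale mode {mode!r}")
    return apply_scaler(matrix, params), params


def apply_scaler(matrix: np.ndarray, params: dict) -> np.ndarray:
    return (np.asarray(matrix, dtype=np.float64) - params["offset"]) / params["scale"]


class Pipeline:
    """Variance filter -> ANOVA selection -> scaling, fit on train rows only.

    ``kept_indices`` composes the two selection stages: indexing the raw
    matrix with it reproduces the unscaled reduced matrix.
    """

    def __init__(self, spec: PreprocessSpec):
        self.spec = spec
        self.kept_indices: np.ndarray | None = None
        self.scaler_params: dict | None = None

    def fit(self, matrix: np.ndarray, labels: np.ndarray) -> "Pipeline":
        reduced, kept_var = variance_filter(matrix, self.spec.variance_threshold)
        if self.spec.n_selected_features is not None:
            n_sel = min(self.spec.n_selected_features, reduced.shape[1])
            reduced, kept_sel = select_features_anova(reduced, labels, n_sel)
            self.kept_indices = kept_var[kept_sel]
        else:
            self.kept_indices = kept_var
        _, self.scaler_params = scale_features(reduced, self.spec.scale)
        return self

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        if self.kept_indices is None or self.scaler_params is None:
            raise RuntimeError("Pipeline.transform called before fit")
        return apply_scaler(np.asarray(matrix)[:, self.kept_indices],
                            self.scaler_params)

    def fit_transform(self, matrix: np.ndarray, labels: np.ndarray) -> np.ndarray:
        return self.fit(matrix, labels).transform(matrix)
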