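"""Dataset and configuration IO.

Omics matrices are CSV/TSV files with a header row of feature names and
the sample ID in the first column; the label file is a two-column table
(sample ID, integer class).  Samples are aligned across files by
intersecting IDs and sorting them lexicographically, so the row order of
a loaded dataset never depends on how the files were written.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .train_eval import ExperimentReport

logger = logging.getLogger("trustomics")


class LoadError(RuntimeError):
    """A data file is missing, unreadable, or malformed."""


class DegenerateInputError(ValueError):
    """The input collapses to something the method cannot run on."""


class ConfigError(ValueError):
    """A configuration value violates its constraints."""


# ---------------------------------------------------------------------------
# dataset container


@dataclass
class MultiOmicsDataset:
    """Aligned per-omics feature matrices with integer class labels.

    All matrices share the same rows (samples) in the same order;
    ``labels[i]`` is the class of ``sample_ids[i]`` and every class in
    ``{0..n_classes-1}`` occurs at least once.
    """

    omics_names: list[str]
    matrices: list[np.ndarray]
    labels: np.ndarray
    sample_ids: list[str]
    n_classes: int
    dropped_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.matrices = [np.asarray(m, dtype=np.float64) for m in self.matrices]
        n = len(self.sample_ids)
        if len(self.omics_names) != len(self.matrices):
            raise ValueError("one matrix per omics name required")
        for name, m in zip(self.omics_names, self.matrices):
            if m.ndim != 2 or m.shape[0] != n:
                raise ValueError(f"omics {name!r}: expected {n} rows, got {m.shape}")
            if not np.isfinite(m).all():
                raise ValueError(f"omics {name!r} contains NaN/Inf entries")
        if self.labels.shape != (n,):
            raise ValueError("labels length must equal the number of samples")
        present = set(np.unique(self.labels).tolist())
        expected = set(range(self.n_classes))
        if not present <= expected or not expected <= present:
            raise ValueError(
                f"labels must cover exactly classes 0..{self.n_classes - 1}, "
                f"found {sorted(present)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_omics(self) -> int:
        return len(self.matrices)

    def select_omics(self, indices: Sequence[int]) -> "MultiOmicsDataset":
        """Sub-dataset containing only the given omics blocks."""
        return MultiOmicsDataset(
            omics_names=[self.omics_names[i] for i in indices],
            matrices=[self.matrices[i].copy() for i in indices],
            labels=self.labels.copy(),
            sample_ids=list(self.sample_ids),
            n_classes=self.n_classes)

    def with_matrix(self, omics_index: int, matrix: np.ndarray) -> "MultiOmicsDataset":
        """Copy of the dataset with one omics matrix replaced."""
        mats = [m.copy() for m in self.matrices]
        mats[omics_index] = np.asarray(matrix, dtype=np.float64)
        return MultiOmicsDataset(
            omics_names=list(self.omics_names), matrices=mats,
            labels=self.labels.copy(), sample_ids=list(self.sample_ids),
            n_classes=self.n_classes)


# ---------------------------------------------------------------------------
# loading / saving


def _read_table(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise LoadError(f"file not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.map(str)
    return df


def _to_numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    try:
        return df.astype(np.float64)
    except (TypeError, ValueError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().nonzero()[0][0]]
                raise LoadError(
                    f"{path}: non-numeric value at row {row!r}, column {col!r}")
        raise LoadError(f"{path}: could not coerce matrix to float")


def load_dataset(omics_paths: Mapping[str, str | Path],
                 label_path: str | Path,
                 impute_missing: bool = False) -> MultiOmicsDataset:
    """Load omics matrices and labels, aligning samples across files.

    Sample IDs are intersected across all omics files and sorted; IDs
    outside the intersection are dropped (and listed on the returned
    dataset as ``dropped_ids``).  Every intersected ID must appear in
    the label file.  Missing values are rejected unless
    ``impute_missing`` enables per-column mean imputation.
    """
    if not omics_paths:
        raise LoadError("at least one omics file is required")
    frames: dict[str, pd.DataFrame] = {}
    for name, path in omics_paths.items():
        path = Path(path)
        df = _to_numeric(_read_table(path), path)
        if df.isna().any().any():
            if impute_missing:
                df = df.fillna(df.mean())
                if df.isna().any().any():
                    raise LoadError(f"{path}: all-NaN column cannot be imputed")
            else:
                raise LoadError(f"{path}: missing values present "
                                "(set impute_missing to mean-impute)")
        frames[name] = df

    label_path = Path(label_path)
    if not label_path.exists():
        raise LoadError(f"file not found: {label_path}")
    sep = "\t" if label_path.suffix.lower() in {".tsv", ".tab"} else ","
    label_df = pd.read_csv(label_path, sep=sep, index_col=0)
    label_df.index = label_df.index.map(str)
    label_series = label_df.iloc[:, 0]

    common = set.intersection(*(set(df.index) for df in frames.values()))
    union = set.union(*(set(df.index) for df in frames.values()))
    kept = sorted(common)
    dropped = tuple(sorted(union - common))
    if len(kept) < 2:
        raise DegenerateInputError(
            f"fewer than 2 samples remain after intersecting IDs ({len(kept)})")
    missing_labels = [s for s in kept if s not in label_series.index]
    if missing_labels:
        raise LoadError(f"label file missing sample IDs: {missing_labels}")
    if dropped:
        logger.info("dropped %d sample IDs not shared by all omics files: %s",
                    len(dropped), ", ".join(dropped))

    labels = label_series.loc[kept].astype(int).to_numpy()
    n_classes = int(labels.max()) + 1
    return MultiOmicsDataset(
        omics_names=list(frames),
        matrices=[frames[name].loc[kept].to_numpy(dtype=np.float64)
                  for name in frames],
        labels=labels,
        sample_ids=kept,
        n_classes=n_classes,
        dropped_ids=dropped)


def save_dataset(dataset: MultiOmicsDataset, out_dir: str | Path,
                 feature_names: Mapping[str, Sequence[str]] | None = None
                 ) -> dict[str, Path]:
    """Write one CSV per omics plus ``labels.csv``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, m in zip(dataset.omics_names, dataset.matrices):
        cols = (list(feature_names[name]) if feature_names and name in feature_names
                else [f"f{j}" for j in range(m.shape[1])])
        df = pd.DataFrame(m, index=dataset.sample_ids, columns=cols)
        df.index.name = "sample_id"
        path = out_dir / f"{name}.csv"
        df.to_csv(path)
        paths[name] = path
    labels = pd.DataFrame({"label": dataset.labels}, index=dataset.sample_ids)
    labels.index.name = "sample_id"
    label_path = out_dir / "labels.csv"
    labels.to_csv(label_path)
    paths["labels"] = label_path
    return paths


# ---------------------------------------------------------------------------
# run configuration


_SIMILARITIES = ("cosine", "euclidean")
_FUSIONS = ("trusted", "mean_evidence")
_STRUCTURES = ("hypergraph", "graph")
_ACTIVATIONS = ("softplus", "relu", "exp")


@dataclass(frozen=True)
class RunConfig:
    """Hyperparameters of one training/evaluation run.

    ``k_neighbors`` is the hyperedge size (each hyperedge holds a sample
    and its k-1 nearest neighbours by cosine similarity);
    ``annealing_step`` is the epoch count over which the wrong-evidence
    penalty weight ramps linearly from 0 to 1.  The ``similarity``,
    ``fusion`` and ``structure`` switches drive the ablation variants.
    """

    k_neighbors: int = 10
    hidden_dims: tuple[int, ...] = (64, 32)
    learning_rate: float = 1e-3
    epochs: int = 500
    annealing_step: int = 50
    seed: int = 0
    test_fraction: float = 0.2
    similarity: str = "cosine"
    fusion: str = "trusted"
    structure: str = "hypergraph"
    leaky_slope: float = 0.01
    evidence_activation: str = "softplus"
    weight_decay: float = 1e-4

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ConfigError("k_neighbors must be >= 1")
        if not self.hidden_dims or any(h < 1 for h in self.hidden_dims):
            raise ConfigError("hidden_dims must be positive integers")
        object.__setattr__(self, "hidden_dims", tuple(int(h) for h in self.hidden_dims))
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.epochs < 1 or self.annealing_step < 1:
            raise ConfigError("epochs and annealing_step must be >= 1")
        if not 0 < self.test_fraction < 1:
            raise ConfigError("test_fraction must lie in (0, 1)")
        for value, allowed, key in ((self.similarity, _SIMILARITIES, "similarity"),
                                    (self.fusion, _FUSIONS, "fusion"),
                                    (self.structure, _STRUCTURES, "structure"),
                                    (self.evidence_activation, _ACTIVATIONS,
                                     "evidence_activation")):
            if value not in allowed:
                raise ConfigError(f"{key} must be one of {allowed}, got {value!r}")
        if not 0 < self.leaky_slope < 1:
            raise ConfigError("leaky_slope must lie in (0, 1)")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hidden_dims"] = list(self.hidden_dims)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping of RunConfig keys")
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update(overrides)
        if "hidden_dims" in raw:
            raw["hidden_dims"] = tuple(raw["hidden_dims"])
        return cls(**raw)


def spawn_seeds(seed: int, names: Sequence[str]) -> dict[str, int]:
    """Fan a single run seed out to named child seeds (all below 2^31).

    Every source of randomness in a run (fold splitting, per-omics
    weight init, noise draws) pulls its seed from here, so one integer
    reproduces the whole run.
    """
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(names, children)}


# ---------------------------------------------------------------------------
# reporting


def format_report(report: "ExperimentReport") -> str:
    """Human-readable per-fold table with mean +/- std per metric."""
    metrics = list(report.mean)
    lines = ["fold  " + "  ".join(f"{m:>12s}" for m in metrics)]
    for i, fold in enumerate(report.per_fold):
        lines.append(f"{i:>4d}  " + "  ".join(f"{fold[m]:12.4f}" for m in metrics))
    mean_row = "  ".join(
        f"{report.mean[m]:.4f}±{(report.std or {}).get(m, 0.0):.4f}".rjust(12)
        for m in metrics)
    lines.append("mean  " + mean_row)
    return "\n".join(lines)


def save_report(report: "ExperimentReport", path: str | Path) -> None:
    """Write a report as JSON plus a sibling ``.txt`` table."""
    if not report.per_fold:
        raise ValueError("cannot save a report with no folds")
    path = Path(path)
    payload = {
        "seed": report.seed,
        "config": report.config_snapshot,
        "per_fold": report.per_fold,
        "mean": report.mean,
        "std": report.std,
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    path.with_suffix(".txt").write_text(format_report(report) + "\n")
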