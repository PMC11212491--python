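"""Synthetic multi-omics fixtures with planted class structure.

Each omics block is drawn from class-conditional Gaussians: a chosen
subset of "informative" columns receives class-specific mean shifts of
magnitude ``effect_size * noise_sd`` on top of N(0, noise_sd^2) noise;
all other columns are pure noise.  Three information layouts are
supported:

redundant
    every omics carries all class contrasts (mimics concordant omics);
complementary
    omics o resolves only class ``o mod b`` — the remaining classes
    share a mean pattern in that block, so no single omics can separate
    all classes but the ensemble can;
one_noisy
    as redundant, except the last omics carries no signal at all
    (effect size 0), emulating a corrupted data source.

Defaults (300 samples, 3 balanced classes, three blocks of 120/100/80
features with 10% informative columns and a 2-SD effect) give a
well-separated problem at desk scale, patterned after the shape of
mRNA / DNA-methylation / miRNA panels after feature selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_config import MultiOmicsDataset

__all__ = ["SyntheticSpec", "generate", "add_gaussian_noise"]

_SPLITS = ("redundant", "complementary", "one_noisy")
_DEFAULT_NAMES = ("mrna", "methylation", "mirna")


@dataclass(frozen=True)
class SyntheticSpec:
    n_samples: int = 300
    n_classes: int = 3
    n_features: tuple[int, ...] = (120, 100, 80)
    informative_fraction: float = 0.1
    effect_size: float = 2.0
    noise_sd: float = 1.0
    information_split: str = "redundant"
    class_proportions: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < self.n_classes:
            raise ValueError("need at least one sample per class")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not self.n_features:
            raise ValueError("need at least one omics block")
        if not 0 < self.informative_fraction <= 1:
            raise ValueError("informative_fraction must lie in (0, 1]")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise ValueError("effect_size >= 0 and noise_sd > 0 required")
        if self.information_split not in _SPLITS:
            raise ValueError(f"information_split must be one of {_SPLITS}")
        if self.class_proportions is not None:
            props = np.asarray(self.class_proportions, dtype=float)
            if props.size != self.n_classes or (props <= 0).any() \
                    or not np.isclose(props.sum(), 1.0):
                raise ValueError("class_proportions must be positive and sum to 1")

    @property
    def omics_names(self) -> tuple[str, ...]:
        m = len(self.n_features)
        if m <= len(_DEFAULT_NAMES):
            return _DEFAULT_NAMES[:m]
        return tuple(f"omics{i}" for i in range(m))


def _draw_labels(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    props = (np.full(spec.n_classes, 1.0 / spec.n_classes)
             if spec.class_proportions is None
             else np.asarray(spec.class_proportions, dtype=float))
    # largest-remainder apportionment keeps counts within 1 of the target
    raw = props * spec.n_samples
    counts = np.floor(raw).astype(int)
    remainder = spec.n_samples - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    labels = np.repeat(np.arange(spec.n_classes), counts)
    return rng.permutation(labels)


def _class_means(spec: SyntheticSpec, omics_index: int, n_informative: int,
                 rng: np.random.Generator) -> np.ndarray:
    """(b x n_informative) mean matrix for one omics block."""
    b = spec.n_classes
    shift = spec.effect_size * spec.noise_sd
    if spec.information_split == "one_noisy" \
            and omics_index == len(spec.n_features) - 1:
        return np.zeros((b, n_informative))
    mu = rng.normal(0.0, shift, size=(b, n_informative))
    if spec.information_split == "complementary":
        # classes other than `own` collapse onto a shared mean pattern
        own = omics_index % b
        shared = rng.normal(0.0, shift, size=n_informative)
        for c in range(b):
            if c != own:
                mu[c] = shared
    return mu


def generate(spec: SyntheticSpec
             ) -> tuple[MultiOmicsDataset, dict[str, dict]]:
    """Draw a dataset plus a manifest of the planted informative columns.

    The manifest maps each omics name to its informative column indices
    and the effective per-block layout; blocks without signal (the
    noisy block of ``one_noisy``) list no informative features.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _draw_labels(spec, rng)
    names = spec.omics_names
    matrices: list[np.ndarray] = []
    manifest: dict[str, dict] = {}
    for o, (name, d) in enumerate(zip(names, spec.n_features)):
        n_inf = max(1, round(spec.informative_fraction * d))
        informative = np.sort(rng.choice(d, size=n_inf, replace=False))
        mu = _class_means(spec, o, n_inf, rng)
        X = rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, d))
        X[:, informative] += mu[labels]
        matrices.append(X)
        carries_signal = bool(np.any(mu != 0.0))
        manifest[name] = {
            "informative_features": (informative.tolist() if carries_signal
                                     else []),
            "information_split": spec.information_split,
            "resolved_class": (o % spec.n_classes
                               if spec.information_split == "complementary"
                               else None),
        }
    dataset = MultiOmicsDataset(
        omics_names=list(names),
        matrices=matrices,
        labels=labels,
        sample_ids=[f"S{i:04d}" for i in range(spec.n_samples)],
        n_classes=spec.n_classes)
    return dataset, manifest


def add_gaussian_noise(matrix: np.ndarray, sigma: float,
                       seed: int) -> np.ndarray:
    """Entrywise additive N(0, sigma^2) noise; sigma = 0 returns a copy."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    matrix = np.asarray(matrix, dtype=np.float64)
    if sigma == 0:
        return matrix.copy()
    rng = np.random.default_rng(seed)
    return matrix + rng.normal(0.0, sigma, size=matrix.shape)
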