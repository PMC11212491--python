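"""Per-omics hypergraph convolutional network.

Stacked spectral convolutions LeakyReLU(Lh @ H @ Z) over the normalized
hypergraph Laplacian, followed by one fully connected layer mapping to
the number of classes and a non-negative evidence head (softplus by
default) so the output can parameterize a Dirichlet via alpha = F + 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["HGCNSpec", "HGCNParams", "EvidenceMatrix", "hgconv_layer",
           "init_params", "forward", "forward_t",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class HGCNSpec:
    """Architecture of one omics network.

    ``hidden_dims`` fixes the number of convolution layers (one per
    entry); the fully connected head always outputs ``n_classes``
    values, passed through ``evidence_activation`` to keep them >= 0.
    """

    input_dim: int
    n_classes: int
    hidden_dims: tuple[int, ...] = (64, 32)
    leaky_slope: float = 0.01
    evidence_activation: str = "softplus"

    def __post_init__(self) -> None:
        if not self.hidden_dims:
            raise ValueError("hidden_dims must be nonempty")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.evidence_activation not in ("softplus", "relu", "exp"):
            raise ValueError(
                f"unknown evidence_activation {self.evidence_activation!r}")


@dataclass
class EvidenceMatrix:
    """Non-negative per-sample, per-class classification evidence F."""

    values: np.ndarray
    omics_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise ValueError("evidence contains non-finite entries")
        if (self.values < 0).any():
            raise ValueError("evidence must be non-negative")


@dataclass
class HGCNParams:
    conv_weights: list[Tensor]
    fc_weight: Tensor
    fc_bias: Tensor

    def all(self) -> list[Tensor]:
        return [*self.conv_weights, self.fc_weight, self.fc_bias]

    def copy(self) -> "HGCNParams":
        clone = lambda t: Tensor(t.data.copy(), requires_grad=True)
        return HGCNParams([clone(w) for w in self.conv_weights],
                          clone(self.fc_weight), clone(self.fc_bias))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(spec: HGCNSpec, seed: int) -> HGCNParams:
    """Glorot-uniform weights, zero biases; deterministic in the seed."""
    rng = np.random.default_rng(seed)
    dims = (spec.input_dim, *spec.hidden_dims)
    conv = [Tensor(_glorot(rng, dims[i], dims[i + 1]), requires_grad=True)
            for i in range(len(spec.hidden_dims))]
    fc_w = Tensor(_glorot(rng, dims[-1], spec.n_classes), requires_grad=True)
    fc_b = Tensor(np.zeros(spec.n_classes), requires_grad=True)
    return HGCNParams(conv, fc_w, fc_b)


def _hgconv_t(Hin: Tensor, Lh: Tensor, Z: Tensor, slope: float) -> Tensor:
    return ad.leaky_relu(Lh @ Hin @ Z, slope)


def hgconv_layer(Hin: np.ndarray, Lh: np.ndarray, Z: np.ndarray,
                 negative_slope: float = 0.01) -> np.ndarray:
    """One convolution layer LeakyReLU(Lh @ Hin @ Z) on plain arrays."""
    Hin, Lh, Z = (np.asarray(a, dtype=np.float64) for a in (Hin, Lh, Z))
    if Lh.shape[1] != Hin.shape[0] or Hin.shape[1] != Z.shape[0]:
        raise ValueError(
            f"shape mismatch: Lh {Lh.shape} @ H {Hin.shape} @ Z {Z.shape}")
    return _hgconv_t(Tensor(Hin), Tensor(Lh), Tensor(Z), negative_slope).data


_HEADS = {"softplus": ad.softplus,
          "relu": lambda t: ad.leaky_relu(t, 0.0),
          "exp": ad.exp}


def forward_t(X: Tensor | np.ndarray, Lh: Tensor | np.ndarray,
              spec: HGCNSpec, params: HGCNParams) -> Tensor:
    """Differentiable forward pass returning the evidence Tensor (n x b)."""
    H = ad.as_tensor(X)
    L = ad.as_tensor(Lh)
    if H.shape[1] != spec.input_dim:
        raise ValueError(f"expected input_dim={spec.input_dim}, got {H.shape[1]}")
    for layer_index, Z in enumerate(params.conv_weights):
        H = _hgconv_t(H, L, Z, spec.leaky_slope)
        if not np.isfinite(H.data).all():
            raise FloatingPointError(
                f"non-finite activations after convolution layer {layer_index}")
    F = _HEADS[spec.evidence_activation](H @ params.fc_weight + params.fc_bias)
    if not np.isfinite(F.data).all():
        raise FloatingPointError("non-finite evidence at output head")
    return F


def forward(X: np.ndarray, Lh: np.ndarray, spec: HGCNSpec,
            params: HGCNParams, omics_id: str = "") -> EvidenceMatrix:
    """Forward pass on plain arrays, returning an EvidenceMatrix."""
    return EvidenceMatrix(forward_t(X, Lh, spec, params).data, omics_id)


# ---------------------------------------------------------------------------
# checkpointing (JSON keeps checkpoints diffable and platform neutral)


def save_checkpoint(path: str | Path, spec: HGCNSpec, params: HGCNParams,
                    seed: int | None = None, extra: dict | None = None) -> None:
    payload = {
        "spec": {"input_dim": spec.input_dim, "n_classes": spec.n_classes,
                 "hidden_dims": list(spec.hidden_dims),
                 "leaky_slope": spec.leaky_slope,
                 "evidence_activation": spec.evidence_activation},
        "seed": seed,
        "conv_weights": [w.data.tolist() for w in params.conv_weights],
        "fc_weight": params.fc_weight.data.tolist(),
        "fc_bias": params.fc_bias.data.tolist(),
        "extra": extra or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> tuple[HGCNSpec, HGCNParams, dict]:
    payload = json.loads(Path(path).read_text())
    s = payload["spec"]
    spec = HGCNSpec(input_dim=s["input_dim"], n_classes=s["n_classes"],
                    hidden_dims=tuple(s["hidden_dims"]),
                    leaky_slope=s["leaky_slope"],
                    evidence_activation=s["evidence_activation"])
    params = HGCNParams(
        [Tensor(np.array(w), requires_grad=True) for w in payload["conv_weights"]],
        Tensor(np.array(payload["fc_weight"]), requires_grad=True),
        Tensor(np.array(payload["fc_bias"]), requires_grad=True))
    meta = {"seed": payload.get("seed"), "extra": payload.get("extra", {})}
    return spec, params, meta
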