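"""Dirichlet opinions, Dempster-Shafer combination, and evidential losses.

Each omics network outputs non-negative evidence F (n x b).  Setting
alpha = F + 1 parameterizes a Dirichlet whose normalized form is an
opinion: per-class confidence p_ij = f_ij / S_i and scalar uncertainty
u_i = b / S_i with S_i = sum_j alpha_ij, so sum_j p_ij + u_i = 1.

Opinions from different omics are combined pairwise by the reduced
Dempster-Shafer rule

    C     = sum_{i != j} p^1_i p^2_j            (conflict mass)
    p_k   = (p^1_k u^2 + p^2_k u^1 + p^1_k p^2_k) / (1 - C)
    u     = u^1 u^2 / (1 - C)

folded left-to-right over the omics list; the fused Dirichlet is
recovered via f_ij = b p_ij / u_i, alpha_ij = f_ij + 1 (the exact
algebraic inverse of the opinion map).

Training minimizes, per opinion, the Dirichlet-expected cross-entropy
sum_j y_ij (psi(S_i) - psi(alpha_ij)) plus an annealed KL penalty
KL(Dir(alpha_tilde) || Dir(1)) on the non-target evidence, where
alpha_tilde = y + (1 - y) * alpha and the weight ramps linearly to 1
over ``annealing_step`` epochs.

All functions run on plain arrays; the ``*_t`` variants operate on
autodiff Tensors and are what training differentiates through.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from . import autodiff as ad
from .autodiff import Tensor
from .hgcn import EvidenceMatrix

__all__ = ["DirichletOpinion", "ConflictError", "opinion_from_evidence",
           "ds_combine_pair", "ds_combine_all", "dirichlet_ce_loss",
           "wrong_evidence_penalty", "tmo_loss", "overall_loss",
           "annealing_weight"]

_CONFLICT_TOL = 1e-12


class ConflictError(ArithmeticError):
    """Two opinions are in (near-)total conflict; combination undefined."""


@dataclass
class DirichletOpinion:
    """Per-sample confidence matrix P, uncertainty vector U, Dirichlet alpha.

    For every sample, sum_j P[i, j] + U[i] = 1 and U[i] > 0.  Source
    opinions have alpha >= 1; fused opinions only alpha > 0.
    """

    P: np.ndarray
    U: np.ndarray
    alpha: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        self.U = np.asarray(self.U, dtype=np.float64).reshape(-1)
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        total = self.P.sum(axis=1) + self.U
        if not np.allclose(total, 1.0, atol=1e-6):
            raise ValueError("opinion violates sum_j p_ij + u_i = 1")
        if (self.U <= 0).any() or (self.P < 0).any() or (self.alpha <= 0).any():
            raise ValueError("opinion requires u > 0, p >= 0, alpha > 0")

    @property
    def n_samples(self) -> int:
        return self.P.shape[0]


def _as_evidence_array(F) -> np.ndarray:
    values = F.values if isinstance(F, EvidenceMatrix) else np.asarray(F)
    values = np.asarray(values, dtype=np.float64)
    if (values < 0).any():
        raise ValueError("evidence must be non-negative")
    return values


# ---------------------------------------------------------------------------
# opinions


def opinion_t(F: Tensor) -> tuple[Tensor, Tensor, Tensor]:
    """Evidence Tensor -> (P, U, alpha) Tensors; U has shape (n, 1)."""
    b = F.shape[1]
    alpha = F + 1.0
    strength = alpha.sum(axis=1, keepdims=True)
    return F / strength, float(b) / strength, alpha


def opinion_from_evidence(F) -> DirichletOpinion:
    """alpha = F + 1; p = f / S; u = b / S with S the Dirichlet strength."""
    values = _as_evidence_array(F)
    P, U, alpha = opinion_t(Tensor(values))
    return DirichletOpinion(P.data, U.data, alpha.data, values.shape[1])


def combine_pair_t(P1: Tensor, U1: Tensor, P2: Tensor, U2: Tensor
                   ) -> tuple[Tensor, Tensor]:
    """Reduced DS combination on Tensors; U inputs/outputs are (n, 1)."""
    conflict = (P1.sum(axis=1, keepdims=True) * P2.sum(axis=1, keepdims=True)
                - (P1 * P2).sum(axis=1, keepdims=True))
    denom_data = 1.0 - conflict.data
    if (denom_data <= _CONFLICT_TOL).any():
        sample = int(np.argmax(denom_data.ravel() <= _CONFLICT_TOL))
        raise ConflictError(
            f"total conflict between opinions at sample {sample}")
    denom = 1.0 - conflict
    P = (P1 * U2 + P2 * U1 + P1 * P2) / denom
    U = U1 * U2 / denom
    return P, U


def fuse_alpha_t(P: Tensor, U: Tensor, n_classes: int) -> Tensor:
    """Recover the fused Dirichlet: f = b p / u, alpha = f + 1 (U is (n, 1))."""
    return float(n_classes) * P / U + 1.0


def _fuse_alpha_np(P: np.ndarray, U: np.ndarray, b: int) -> np.ndarray:
    return fuse_alpha_t(Tensor(P), Tensor(U.reshape(-1, 1)), b).data


def ds_combine_pair(op1: DirichletOpinion, op2: DirichletOpinion
                    ) -> DirichletOpinion:
    """Combine two opinions by the reduced Dempster-Shafer rule."""
    if op1.n_classes != op2.n_classes or op1.n_samples != op2.n_samples:
        raise ValueError("opinions must share sample count and class count")
    P, U = combine_pair_t(Tensor(op1.P), Tensor(op1.U.reshape(-1, 1)),
                          Tensor(op2.P), Tensor(op2.U.reshape(-1, 1)))
    P, U = P.data, U.data.reshape(-1)
    return DirichletOpinion(P, U, _fuse_alpha_np(P, U, op1.n_classes),
                            op1.n_classes)


def ds_combine_all(opinions: list[DirichletOpinion]) -> DirichletOpinion:
    """Left fold of the pairwise rule over the omics list (>= 1 opinion)."""
    if not opinions:
        raise ValueError("need at least one opinion")
    fused = opinions[0]
    for op in opinions[1:]:
        fused = ds_combine_pair(fused, op)
    return fused


# ---------------------------------------------------------------------------
# losses


def _mask_vector(mask, n: int) -> np.ndarray:
    if mask is None:
        return np.ones((n, 1))
    mask = np.asarray(mask)
    if mask.dtype == bool:
        out = mask.astype(np.float64)
    else:  # index array
        out = np.zeros(n)
        out[mask] = 1.0
    if out.sum() == 0:
        raise ValueError("sample_mask selects no samples")
    return out.reshape(-1, 1)


def _check_targets(alpha_shape: tuple[int, ...], y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    if y.shape != alpha_shape:
        raise ValueError(f"one-hot labels {y.shape} must match alpha {alpha_shape}")
    return y


def dirichlet_ce_loss_t(alpha: Tensor, y: np.ndarray,
                        sample_mask=None) -> Tensor:
    """Masked mean of sum_j y_ij (psi(S_i) - psi(alpha_ij))."""
    y = _check_targets(alpha.shape, y)
    if (alpha.data <= 0).any():
        raise ValueError("Dirichlet parameters must be positive")
    m = _mask_vector(sample_mask, alpha.shape[0])
    strength = alpha.sum(axis=1, keepdims=True)
    per_sample = (Tensor(y) * (ad.digamma(strength) - ad.digamma(alpha))
                  ).sum(axis=1, keepdims=True)
    return (per_sample * m).sum() * (1.0 / m.sum())


def wrong_evidence_penalty_t(alpha: Tensor, y: np.ndarray,
                             sample_mask=None) -> Tensor:
    """Masked mean KL(Dir(alpha_tilde) || Dir(1)), alpha_tilde = y + (1-y)alpha.

    Zero exactly when all non-target evidence is zero; strictly
    increasing in any non-target alpha.
    """
    y = _check_targets(alpha.shape, y)
    b = alpha.shape[1]
    m = _mask_vector(sample_mask, alpha.shape[0])
    at = Tensor(y) + Tensor(1.0 - y) * alpha
    st = at.sum(axis=1, keepdims=True)
    kl = (ad.lgamma(st) - ad.lgamma(at).sum(axis=1, keepdims=True)
          - special.gammaln(b)
          + ((at - 1.0) * (ad.digamma(at) - ad.digamma(st))
             ).sum(axis=1, keepdims=True))
    return (kl * m).sum() * (1.0 / m.sum())


def annealing_weight(epoch: int, annealing_step: int) -> float:
    """Penalty weight lambda: linear ramp from 0 to 1 over annealing_step."""
    if annealing_step < 1:
        raise ValueError("annealing_step must be >= 1")
    return min(1.0, epoch / annealing_step)


def tmo_loss_t(alpha: Tensor, y: np.ndarray, sample_mask,
               epoch: int, annealing_step: int) -> Tensor:
    lam = annealing_weight(epoch, annealing_step)
    loss = dirichlet_ce_loss_t(alpha, y, sample_mask)
    if lam > 0:
        loss = loss + lam * wrong_evidence_penalty_t(alpha, y, sample_mask)
    return loss


def overall_loss_t(per_omics_alphas: list[Tensor], fused_alpha: Tensor,
                   y: np.ndarray, sample_mask, epoch: int,
                   annealing_step: int) -> Tensor:
    """Annealed loss on the fused opinion plus every per-omics opinion."""
    loss = tmo_loss_t(fused_alpha, y, sample_mask, epoch, annealing_step)
    for alpha in per_omics_alphas:
        loss = loss + tmo_loss_t(alpha, y, sample_mask, epoch, annealing_step)
    return loss


# plain-array wrappers ------------------------------------------------------


def dirichlet_ce_loss(alpha, y, sample_mask=None) -> float:
    return dirichlet_ce_loss_t(ad.as_tensor(alpha), y, sample_mask).item()


def wrong_evidence_penalty(alpha, y, sample_mask=None) -> float:
    return wrong_evidence_penalty_t(ad.as_tensor(alpha), y, sample_mask).item()


def tmo_loss(alpha, y, sample_mask=None, epoch: int = 0,
             annealing_step: int = 1) -> float:
    return tmo_loss_t(ad.as_tensor(alpha), y, sample_mask,
                      epoch, annealing_step).item()


def overall_loss(per_omics_alphas, fused_alpha, y, sample_mask=None,
                 epoch: int = 0, annealing_step: int = 1) -> float:
    return overall_loss_t([ad.as_tensor(a) for a in per_omics_alphas],
                          ad.as_tensor(fused_alpha), y, sample_mask,
                          epoch, annealing_step).item()


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out
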