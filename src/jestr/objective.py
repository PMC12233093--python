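"""Training objectives for the joint embedding space.

The discriminator scores a spectrum-molecule pair with a temperature-scaled
exponentiated cosine, h(z_spec, z_mol) = exp(cos(z_spec, z_mol) / tau).
The contrastive loss is InfoNCE over a batch of k matched pairs: each
spectrum is the anchor and all k molecules in the batch (including its
match) form the softmax denominator.  The regularization loss is the mean
cosine between each spectrum and the formula-matched candidates of its
target; minimizing it pushes decoys away from the spectra during the final
fine-tuning phase.  The total loss is alpha * L_contrastive +
beta * L_regularization with (alpha, beta) = (1.0, 0.0) for the first 97%
of epochs and (0.9, 0.1) for the last 3%.

A cross-entropy-on-dot-products variant is provided for ablation: unlike
the cosine form it is sensitive to embedding magnitudes.

All losses accept either plain arrays (returning floats) or autodiff
Tensors (returning differentiable scalars used by the training loop).
Natural logarithms throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .encoders import Embedding


@dataclass
class ObjectiveConfig:
    """Loss hyperparameters.

    ``temperature`` sharpens the positive/negative contrast (smaller =>
    sharper).  ``reg_weight`` is beta during the fine-tuning phase;
    ``reg_start_fraction`` is the fraction of epochs trained before
    regularization switches on (alpha + beta = 1 throughout).
    """

    temperature: float = 0.07
    reg_weight: float = 0.1
    reg_start_fraction: float = 0.97
    loss_variant: Literal["infonce_cosine", "ce_dotproduct"] = "infonce_cosine"
    symmetric: bool = False

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0.0 <= self.reg_weight <= 1.0:
            raise ValueError("reg_weight must be in [0, 1]")
        if not 0.0 < self.reg_start_fraction <= 1.0:
            raise ValueError("reg_start_fraction must be in (0, 1]")


def _to_matrix(x) -> np.ndarray:
    """Coerce embeddings (list of Embedding, array, Tensor) to (k, d) array."""
    if isinstance(x, Tensor):
        return x.data
    if isinstance(x, Embedding):
        return x.vector[None, :]
    if isinstance(x, (list, tuple)) and x and isinstance(x[0], Embedding):
        return np.stack([e.vector for e in x])
    return np.atleast_2d(np.asarray(x, dtype=float))


def _check_nonzero(mat: np.ndarray, what: str) -> None:
    norms = np.linalg.norm(mat, axis=1)
    if np.any(norms == 0):
        raise ValueError(f"cosine undefined: zero {what} embedding in batch")


def discriminator(z_spec, z_mol, tau: float) -> float:
    """exp(cos(z_spec, z_mol) / tau); invariant to positive rescaling."""
    if tau <= 0:
        raise ValueError("temperature tau must be positive")
    a = np.asarray(getattr(z_spec, "vector", z_spec), dtype=float).ravel()
    b = np.asarray(getattr(z_mol, "vector", z_mol), dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine undefined for a zero embedding")
    return float(np.exp((a @ b) / (na * nb) / tau))


def _cosine_matrix_t(a: Tensor, b: Tensor) -> Tensor:
    return ad.l2_normalize_rows(a) @ ad.l2_normalize_rows(b).T


def _infonce_t(spec: Tensor, mol: Tensor, tau: float) -> Tensor:
    k = spec.shape[0]
    logits = _cosine_matrix_t(spec, mol) * (1.0 / tau)
    eye = Tensor(np.eye(k))
    pos = (logits * eye).sum(axis=1, keepdims=True)
    return (ad.logsumexp_rows(logits) - pos).mean()


def contrastive_loss(spec_embs, mol_embs, tau: float) -> float | Tensor:
    """InfoNCE over k matched (spectrum, molecule) pairs; natural log.

    Spectra are the anchors; the denominator for spectrum n runs over all
    k molecules in the batch.  Returns 0 exactly for k = 1.
    """
    if tau <= 0:
        raise ValueError("temperature tau must be positive")
    if isinstance(spec_embs, Tensor) and isinstance(mol_embs, Tensor):
        if spec_embs.shape[0] != mol_embs.shape[0] or spec_embs.shape[0] == 0:
            raise ValueError("need equal, nonzero counts of paired embeddings")
        return _infonce_t(spec_embs, mol_embs, tau)
    spec = _to_matrix(spec_embs)
    mol = _to_matrix(mol_embs)
    if spec.shape[0] != mol.shape[0] or spec.shape[0] == 0:
        raise ValueError("need equal, nonzero counts of paired embeddings")
    _check_nonzero(spec, "spectrum")
    _check_nonzero(mol, "molecule")
    return float(_infonce_t(Tensor(spec), Tensor(mol), tau).data)


def regularization_loss(spec_embs, cand_embs, owners=None) -> float | Tensor:
    """Mean cosine between each spectrum and its target's candidates.

    ``cand_embs`` is either a (k, kaug, d) block (every spectrum the same
    number of candidates) or a flat (M, d) matrix with ``owners`` mapping
    each row to its spectrum index.  Every spectrum must own at least one
    candidate; batches containing candidate-free targets must drop those
    spectra before calling (the batcher does).  Result lies in [-1, 1];
    it is not clamped below zero — the objective is literally to minimize
    the mean cosine.
    """
    tensor_mode = isinstance(spec_embs, Tensor)
    spec = spec_embs if tensor_mode else Tensor(_to_matrix(spec_embs))
    k = spec.shape[0]
    if owners is None:
        arr = cand_embs if isinstance(cand_embs, Tensor) else Tensor(
            np.asarray(
                [[_e.vector for _e in row] if row and isinstance(row[0], Embedding) else row
                 for row in cand_embs]
                if isinstance(cand_embs, (list, tuple))
                else cand_embs,
                dtype=float,
            )
        )
        if arr.data.ndim != 3 or arr.shape[0] != k or arr.shape[1] == 0:
            raise ValueError("candidate block must be (k, kaug>=1, d)")
        kaug = arr.shape[1]
        flat = Tensor(arr.data.reshape(k * kaug, -1), requires_grad=arr.requires_grad,
                      parents=(arr,))
        flat._backward = lambda g, _a=arr: _a.requires_grad and _a._accum(
            g.reshape(_a.shape)
        )
        owners_arr = np.repeat(np.arange(k), kaug)
        cand = flat
    else:
        cand = cand_embs if isinstance(cand_embs, Tensor) else Tensor(_to_matrix(cand_embs))
        owners_arr = np.asarray(owners, dtype=int)
        if len(owners_arr) != cand.shape[0]:
            raise ValueError("owners length must match candidate count")
    counts = np.bincount(owners_arr, minlength=k).astype(float)
    if np.any(counts == 0):
        raise ValueError(
            "every spectrum in the batch needs at least one candidate "
            "for the regularization term"
        )
    if not tensor_mode:
        _check_nonzero(spec.data, "spectrum")
        _check_nonzero(cand.data, "candidate")
    spec_n = ad.l2_normalize_rows(spec)
    cand_n = ad.l2_normalize_rows(cand)
    cos = (ad.gather(spec_n, owners_arr) * cand_n).sum(axis=1)
    per_spec = ad.segment_sum(cos, owners_arr, k) / Tensor(counts)
    out = per_spec.mean()
    return out if tensor_mode else float(out.data)


def schedule_weights(epoch: int, total_epochs: int, cfg: ObjectiveConfig) -> tuple[float, float]:
    """(alpha, beta) for a 1-based epoch under the two-phase schedule.

    Regularization activates for epochs strictly after
    floor(reg_start_fraction * total_epochs); for short runs the final
    epoch alone is regularized so the fine-tuning phase is never empty.
    """
    if not 1 <= epoch <= total_epochs:
        raise ValueError(f"epoch {epoch} outside 1..{total_epochs}")
    boundary = min(math.floor(cfg.reg_start_fraction * total_epochs), total_epochs - 1)
    if epoch > boundary:
        return 1.0 - cfg.reg_weight, cfg.reg_weight
    return 1.0, 0.0


def total_loss(Lc, Lr, epoch: int, total_epochs: int, cfg: ObjectiveConfig):
    """alpha * Lc + beta * Lr under the schedule; returns (value, alpha, beta)."""
    alpha, beta = schedule_weights(epoch, total_epochs, cfg)
    if isinstance(Lc, Tensor) or isinstance(Lr, Tensor):
        value = ad._as_tensor(Lc) * alpha + ad._as_tensor(Lr) * beta
    else:
        value = alpha * float(Lc) + beta * float(Lr)
    return value, alpha, beta


def _ce_dot_t(spec: Tensor, mol: Tensor) -> Tensor:
    k = spec.shape[0]
    logits = spec @ mol.T
    eye = Tensor(np.eye(k))
    pos = (logits * eye).sum(axis=1, keepdims=True)
    return (ad.logsumexp_rows(logits) - pos).mean()


def ce_dotproduct_loss(spec_embs, mol_embs) -> float | Tensor:
    """Cross-entropy over softmaxed in-batch dot products (ablation).

    Coincides with :func:`contrastive_loss` at tau = 1 when all embeddings
    are unit-norm, but unlike the cosine form it is NOT invariant to
    rescaling individual embeddings.
    """
    if isinstance(spec_embs, Tensor) and isinstance(mol_embs, Tensor):
        if spec_embs.shape[0] != mol_embs.shape[0] or spec_embs.shape[0] == 0:
            raise ValueError("need equal, nonzero counts of paired embeddings")
        return _ce_dot_t(spec_embs, mol_embs)
    spec = _to_matrix(spec_embs)
    mol = _to_matrix(mol_embs)
    if spec.shape[0] != mol.shape[0] or spec.shape[0] == 0:
        raise ValueError("need equal, nonzero counts of paired embeddings")
    return float(_ce_dot_t(Tensor(spec), Tensor(mol)).data)


def batch_loss(spec: Tensor, mol: Tensor, cfg: ObjectiveConfig) -> Tensor:
    """Dispatch on the configured pairing-loss variant (training path)."""
    if cfg.loss_variant == "ce_dotproduct":
        loss = _ce_dot_t(spec, mol)
        if cfg.symmetric:
            loss = (loss + _ce_dot_t(mol, spec)) * 0.5
        return loss
    loss = _infonce_t(spec, mol, cfg.temperature)
    if cfg.symmetric:
        loss = (loss + _infonce_t(mol, spec, cfg.temperature)) * 0.5
    return loss
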