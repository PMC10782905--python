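"""Loss functions for imbalanced per-residue classification.

Three pieces compose the training objective:

* **Effective number** ``E_n = (1 - beta^n) / (1 - beta)`` — a saturating
  measure of how much coverage ``n`` samples of a class provide; its
  reciprocal, ``w_y = (1 - beta) / (1 - beta^{n_y})``, up-weights the minority
  class.
* **Class-balanced focal loss** — cross-entropy scaled by the focusing
  modulator ``(1 - p_t)^gamma`` and by the effective-number class weight, so
  confidently classified residues and over-represented classes contribute
  less.
* **Triplet center loss (TCL)** — a hinge pulling each residue's feature
  vector toward its own learnable class center and pushing it at least a
  margin ``m`` (in half-squared-Euclidean distance) away from the nearest
  other-class center.

The joint objective is ``L = L_focal + lambda * L_tc``.  Class counts are
global training-set residue counts, not per-batch tallies.  Both losses are
averaged over real (masked-in) residues so their scale is batch-size
invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

#: floor applied to probabilities before taking logs
PROB_EPS = 1e-8


class LossError(ValueError):
    pass


@dataclass(frozen=True)
class ClassCounts:
    """Global training-set residue counts per class (0 = non-binding, 1 = binding)."""

    n_neg: int
    n_pos: int

    def __post_init__(self) -> None:
        if self.n_neg < 1 or self.n_pos < 1:
            raise LossError("both class counts must be >= 1")

    def __getitem__(self, cls: int) -> int:
        return (self.n_neg, self.n_pos)[cls]


@dataclass(frozen=True)
class LossConfig:
    """All loss hyperparameters, with reference defaults for the binding task.

    beta: effective-number saturation (0.999); gamma: focal focusing exponent
    (5); lambda_: weight of the TCL term in the joint objective (0.1);
    margin: TCL hinge margin in half-squared-Euclidean distance units (9);
    center_lr: learning rate of the centers' own optimizer (0.01);
    tcl_feature_layer: index of the backbone block whose output feeds the TCL
    (default 2, the 64-dim penultimate block), or the string "probs" to run
    the TCL on the softmax probabilities.
    """

    beta: float = 0.999
    gamma: float = 5.0
    lambda_: float = 0.1
    margin: float = 9.0
    center_lr: float = 0.01
    tcl_feature_layer: int | str = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta < 1.0):
            raise LossError("beta must be in [0, 1)")
        if self.gamma < 0:
            raise LossError("gamma must be >= 0")
        if self.lambda_ < 0:
            raise LossError("lambda_ must be >= 0")
        if self.margin < 0:
            raise LossError("margin must be >= 0")
        if self.center_lr <= 0:
            raise LossError("center_lr must be > 0")

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "gamma": self.gamma,
            "lambda_": self.lambda_,
            "margin": self.margin,
            "center_lr": self.center_lr,
            "tcl_feature_layer": self.tcl_feature_layer,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LossConfig":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


class CenterBank:
    """Learnable per-class center vectors in the contrastive feature space.

    Randomly initialized (seeded standard normal) and updated only by its own
    SGD optimizer at ``center_lr``.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        self.centers = rng.standard_normal((2, dim))
        self.grad = np.zeros_like(self.centers)

    @property
    def dim(self) -> int:
        return self.centers.shape[1]

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    def sgd_step(self, lr: float) -> None:
        self.centers -= lr * self.grad


def effective_number(n: int, beta: float) -> float:
    """E_n = (1 - beta^n) / (1 - beta); strictly increasing in n, -> 1/(1-beta)."""
    if n < 1:
        raise LossError("n must be >= 1")
    if not (0.0 <= beta < 1.0):
        raise LossError("beta must be in [0, 1)")
    if beta == 0.0:
        return 1.0
    return float((1.0 - beta**n) / (1.0 - beta))


def class_weights(counts: ClassCounts, beta: float, normalize: bool = True) -> np.ndarray:
    """Per-class weights w_y proportional to 1 / E_{n_y}.

    The rarer class always gets the larger weight.  Following the standard
    class-balanced construction, the weights are normalized to sum to the
    number of classes, which keeps the loss on the cross-entropy scale
    regardless of dataset size (raw 1/E_n weights shrink like (1-beta) for
    large counts, which would silently rescale the focal term against the
    contrastive term in the joint objective).
    """
    w = np.array(
        [1.0 / effective_number(counts.n_neg, beta), 1.0 / effective_number(counts.n_pos, beta)]
    )
    if normalize:
        w = w * (2.0 / w.sum())
    return w


def _clamp_probs(p: np.ndarray) -> np.ndarray:
    if np.any(p <= 0.0):
        warnings.warn(
            f"true-class probabilities of 0 clamped to {PROB_EPS:g} before log",
            stacklevel=3,
        )
        return np.clip(p, PROB_EPS, 1.0)
    return p


def cb_focal_loss(
    p_true: np.ndarray,
    labels: np.ndarray,
    counts: ClassCounts,
    cfg: LossConfig,
    mask: np.ndarray | None = None,
    reduction: str = "mean",
) -> float:
    """Class-balanced focal loss over residues.

    ``p_true[i]`` is the model probability assigned to residue *i*'s TRUE
    class.  Each residue contributes
    ``w_{y_i} * (1 - p_true[i])^gamma * (-log p_true[i])`` with the
    normalized effective-number class weight ``w_y`` (proportional to
    ``(1 - beta) / (1 - beta^{n_y})``, summing to 2 over the classes); the
    result is the mean (or sum) over masked-in residues.  Zero iff every
    ``p_true`` equals 1.
    """
    p_true = np.asarray(p_true, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if p_true.shape != labels.shape:
        raise LossError("p_true and labels must have the same length")
    if mask is None:
        mask = np.ones_like(labels, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool).ravel()
    if not mask.any():
        raise LossError("mask selects no residues")
    p = _clamp_probs(p_true[mask])
    y = labels[mask]
    w = class_weights(counts, cfg.beta)[y]
    per_residue = w * (1.0 - p) ** cfg.gamma * (-np.log(p))
    if reduction == "mean":
        return float(per_residue.mean())
    if reduction == "sum":
        return float(per_residue.sum())
    raise LossError(f"unknown reduction {reduction!r}")


def cb_focal_loss_grad(
    logits: np.ndarray,
    labels: np.ndarray,
    counts: ClassCounts,
    cfg: LossConfig,
    mask: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the (B, L, 2) logits.

    With p = softmax(z) and t the true class,
    dL/dp_t = w * [gamma (1-p_t)^{gamma-1} log p_t - (1-p_t)^gamma / p_t]
    and dL/dz_j = dL/dp_t * p_t (delta_{tj} - p_j); mean reduction over the
    masked residues.
    """
    from .backbone import softmax  # local import to avoid a cycle

    probs = softmax(logits)
    y = np.asarray(labels, dtype=int)
    n = int(mask.sum())
    if n == 0:
        raise LossError("mask selects no residues")
    # upper clip keeps (1-p)^(gamma-1) finite for gamma < 1 at p == 1
    p_t = np.clip(
        np.take_along_axis(probs, y[..., None], axis=-1)[..., 0], PROB_EPS, 1.0 - 1e-12
    )
    w = class_weights(counts, cfg.beta)[y]
    one_m = 1.0 - p_t
    logp = np.log(p_t)
    loss_terms = w * one_m**cfg.gamma * (-logp)
    loss = float(loss_terms[mask].sum() / n)

    if cfg.gamma == 0.0:
        dl_dpt = -w / p_t
    else:
        dl_dpt = w * (cfg.gamma * one_m ** (cfg.gamma - 1.0) * logp - one_m**cfg.gamma / p_t)
    dl_dpt = dl_dpt * mask / n
    # dp_t/dz_j = p_t (delta_{tj} - p_j)
    delta = np.zeros_like(probs)
    np.put_along_axis(delta, y[..., None], 1.0, axis=-1)
    dlogits = dl_dpt[..., None] * p_t[..., None] * (delta - probs)
    return loss, dlogits


def tcl_distances(features: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Half-squared-Euclidean distances D(f_i, c_j) = 0.5 ||f_i - c_j||^2, (M, 2)."""
    diff = features[:, None, :] - centers[None, :, :]
    return 0.5 * np.einsum("mjk,mjk->mj", diff, diff)


def triplet_center_loss(
    features: np.ndarray,
    labels: np.ndarray,
    bank: CenterBank | np.ndarray,
    margin: float,
    mask: np.ndarray | None = None,
    reduction: str = "mean",
) -> float:
    """Hinge on own-center vs nearest other-center half-squared distances.

    Each residue contributes
    ``max(D(f_i, c_{y_i}) + m - min_{j != y_i} D(f_i, c_j), 0)``; with two
    classes the min is over the single other center.
    """
    centers = bank.centers if isinstance(bank, CenterBank) else np.asarray(bank)
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int).ravel()
    if features.ndim != 2 or features.shape[0] != labels.shape[0]:
        raise LossError("features must be (M, K) aligned with labels")
    if mask is None:
        mask = np.ones_like(labels, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool).ravel()
    if not mask.any():
        raise LossError("mask selects no residues")
    f, y = features[mask], labels[mask]
    d = tcl_distances(f, centers)
    d_own = d[np.arange(len(y)), y]
    d_other = d[np.arange(len(y)), 1 - y]
    hinge = np.maximum(d_own + margin - d_other, 0.0)
    if reduction == "mean":
        return float(hinge.mean())
    if reduction == "sum":
        return float(hinge.sum())
    raise LossError(f"unknown reduction {reduction!r}")


def triplet_center_loss_grad(
    features: np.ndarray,
    labels: np.ndarray,
    bank: CenterBank,
    margin: float,
    mask: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss plus gradients w.r.t. the flattened (M, K) features and the centers.

    Where the hinge is active, dL/df_i = c_other - c_own,
    dL/dc_own = -(f_i - c_own), dL/dc_other = +(f_i - c_other);
    mean reduction over masked residues.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int).ravel()
    mask = np.asarray(mask, dtype=bool).ravel()
    n = int(mask.sum())
    if n == 0:
        raise LossError("mask selects no residues")
    centers = bank.centers
    d = tcl_distances(features, centers)
    idx = np.arange(features.shape[0])
    d_own = d[idx, labels]
    d_other = d[idx, 1 - labels]
    hinge = d_own + margin - d_other
    active = (hinge > 0.0) & mask
    loss = float(np.maximum(hinge, 0.0)[mask].sum() / n)

    dfeat = np.zeros_like(features)
    dcenters = np.zeros_like(centers)
    if active.any():
        c_own = centers[labels[active]]
        c_other = centers[1 - labels[active]]
        f_act = features[active]
        dfeat[active] = (c_other - c_own) / n
        for cls in (0, 1):
            own_sel = labels[active] == cls
            dcenters[cls] -= (f_act[own_sel] - centers[cls]).sum(axis=0) / n
            dcenters[cls] += (f_act[~own_sel] - centers[cls]).sum(axis=0) / n
    return loss, dfeat, dcenters


def joint_loss(focal: float, tcl: float, lambda_: float) -> float:
    """Joint objective L = L_focal + lambda * L_tc; lambda = 0 recovers pure focal."""
    if not (np.isfinite(focal) and np.isfinite(tcl)):
        raise LossError("loss components must be finite")
    return float(focal + lambda_ * tcl)
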