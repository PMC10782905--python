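"""Joint optimization of the classifier and the contrastive center bank.

Two optimizer groups: the backbone parameters use Adam at ``model_lr``; the
class centers use their own plain SGD optimizer at ``center_lr``.  Embeddings
are frozen inputs — no gradient ever reaches them.  Training is fully
reproducible given the seed: initialization, shuffling and dropout each draw
from independent child streams of one seed sequence, so e.g. a run with
``lambda_ = 0`` follows exactly the same parameter trajectory as a focal-only
run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .backbone import Backbone, BackboneConfig, PredictionTrack, batchify, softmax
from .embedding import EmbeddingMatrix
from .losses import (
    CenterBank,
    ClassCounts,
    LossConfig,
    cb_focal_loss_grad,
    joint_loss,
    triplet_center_loss_grad,
)
from .metrics import roc_pr_curves
from .seqio import LabeledDataset


class TrainerError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    model_lr: float = 1e-3
    epochs: int = 50
    batch_size: int = 16
    seed: int = 0
    threshold: float = 0.5
    validation_fraction: float = 0.0  # >0 enables a seeded held-out split
    early_stop_patience: int | None = None  # epochs without val-AUC gain before stopping

    def __post_init__(self) -> None:
        if self.model_lr <= 0:
            raise TrainerError("model_lr must be > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise TrainerError("epochs and batch_size must be >= 1")
        if not (0.0 < self.threshold < 1.0):
            raise TrainerError("threshold must be in (0, 1)")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise TrainerError("validation_fraction must be in [0, 1)")
        if self.early_stop_patience is not None:
            if self.early_stop_patience < 1:
                raise TrainerError("early_stop_patience must be >= 1")
            if self.validation_fraction == 0.0:
                raise TrainerError("early stopping requires a validation split")

    def to_dict(self) -> dict:
        return {
            "model_lr": self.model_lr,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "seed": self.seed,
            "threshold": self.threshold,
            "validation_fraction": self.validation_fraction,
            "early_stop_patience": self.early_stop_patience,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrainConfig":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


class Adam:
    """Adaptive-moment optimizer over a named parameter dict."""

    def __init__(self, params: Mapping[str, "np.ndarray"], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = dict(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = {k: np.zeros_like(p.value) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in self.params.items()}

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad**2
            p.value -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


@dataclass
class TrainedModel:
    """A trained backbone plus its center bank and configuration."""

    backbone: Backbone
    centers: CenterBank
    backbone_cfg: BackboneConfig
    loss_cfg: LossConfig
    train_cfg: TrainConfig
    counts: ClassCounts

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        state = self.backbone.state_dict()
        state["centers"] = self.centers.centers.copy()
        np.savez(out / "weights.npz", **state)
        with open(out / "model.json", "w") as fh:
            json.dump(
                {
                    "backbone": self.backbone_cfg.to_dict(),
                    "loss": self.loss_cfg.to_dict(),
                    "train": self.train_cfg.to_dict(),
                    "counts": {"n_neg": self.counts.n_neg, "n_pos": self.counts.n_pos},
                },
                fh,
                indent=2,
            )
        return out

    @classmethod
    def load(cls, out_dir: str | Path) -> "TrainedModel":
        out = Path(out_dir)
        with open(out / "model.json") as fh:
            meta = json.load(fh)
        backbone_cfg = BackboneConfig.from_dict(meta["backbone"])
        loss_cfg = LossConfig.from_dict(meta["loss"])
        train_cfg = TrainConfig.from_dict(meta["train"])
        counts = ClassCounts(**meta["counts"])
        backbone = Backbone(backbone_cfg, np.random.default_rng(0))
        with np.load(out / "weights.npz") as data:
            state = {k: data[k] for k in data.files}
        centers_arr = state.pop("centers")
        backbone.load_state_dict(state)
        centers = CenterBank(centers_arr.shape[1], np.random.default_rng(0))
        centers.centers[...] = centers_arr
        return cls(backbone, centers, backbone_cfg, loss_cfg, train_cfg, counts)


def _tcl_feature_dim(backbone_cfg: BackboneConfig, loss_cfg: LossConfig) -> int:
    layer = loss_cfg.tcl_feature_layer
    if layer == "probs":
        return 2
    if not (0 <= int(layer) <= 3):
        raise TrainerError("tcl_feature_layer must be a block index 0..3 or 'probs'")
    return backbone_cfg.layer_dims[int(layer)]


def _epoch_batches(ids: list[str], batch_size: int, rng: np.random.Generator):
    order = rng.permutation(len(ids))
    for start in range(0, len(ids), batch_size):
        yield [ids[i] for i in order[start : start + batch_size]]


def _joint_loss_and_backward(
    backbone: Backbone,
    centers: CenterBank,
    x: np.ndarray,
    mask: np.ndarray,
    labels: np.ndarray,
    counts: ClassCounts,
    loss_cfg: LossConfig,
    drop_rng: np.random.Generator,
) -> tuple[float, float]:
    """One train-mode forward/backward; returns (focal, tcl) loss values."""
    res = backbone.forward(x, mask, train=True, rng=drop_rng)
    focal, dlogits = cb_focal_loss_grad(res.logits, labels, counts, loss_cfg, mask)

    tcl_val = 0.0
    feature_grads: dict[int, np.ndarray] = {}
    if loss_cfg.lambda_ > 0.0:
        layer = loss_cfg.tcl_feature_layer
        if layer == "probs":
            feats3d = res.probs
        else:
            feats3d = res.features[int(layer)]
        b, l, k = feats3d.shape
        flat = feats3d.reshape(b * l, k)
        tcl_val, dfeat_flat, dcenters = triplet_center_loss_grad(
            flat, labels.reshape(-1), centers, loss_cfg.margin, mask.reshape(-1)
        )
        centers.grad += loss_cfg.lambda_ * dcenters
        dfeat = loss_cfg.lambda_ * dfeat_flat.reshape(b, l, k)
        if layer == "probs":
            # route the probability-space gradient through the softmax jacobian
            p = res.probs
            dot = np.sum(dfeat * p, axis=-1, keepdims=True)
            dlogits = dlogits + p * (dfeat - dot)
        elif int(layer) == 3:
            dlogits = dlogits + dfeat
        else:
            feature_grads[int(layer)] = dfeat

    backbone.backward(dlogits, feature_grads)
    return focal, tcl_val


@dataclass
class TrainLog:
    """Per-epoch training history (mean batch losses and validation metrics)."""

    epochs: list[dict] = field(default_factory=list)

    def append(self, **row) -> None:
        self.epochs.append(row)

    def write_tsv(self, path: str | Path) -> None:
        if not self.epochs:
            return
        cols = list(self.epochs[0])
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in self.epochs:
                fh.write("\t".join(f"{row[c]:.6g}" if isinstance(row[c], float)
                                   else str(row[c]) for c in cols) + "\n")


def train(
    ds: LabeledDataset,
    embeddings: Mapping[str, EmbeddingMatrix],
    backbone_cfg: BackboneConfig,
    loss_cfg: LossConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> tuple[TrainedModel, TrainLog]:
    """Train the classifier and the center bank jointly on a labeled dataset.

    Every record must have a cached embedding; class counts for the
    effective-number weights are tallied globally over the training labels.
    """
    loss_cfg = loss_cfg or LossConfig()
    train_cfg = train_cfg or TrainConfig()

    for rec in ds.records:
        if rec.id not in embeddings:
            raise TrainerError(f"missing embedding for id {rec.id!r}")
        if embeddings[rec.id].length != len(rec):
            raise TrainerError(f"id {rec.id!r}: embedding rows != sequence length")
        if embeddings[rec.id].dim != backbone_cfg.in_dim:
            raise TrainerError(
                f"id {rec.id!r}: embedding dim {embeddings[rec.id].dim} != "
                f"backbone in_dim {backbone_cfg.in_dim}"
            )

    ss = np.random.SeedSequence(train_cfg.seed)
    init_rng, center_rng, shuffle_rng, drop_rng, split_rng = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    ids = [r.id for r in ds.records]
    val_ids: list[str] = []
    if train_cfg.validation_fraction > 0.0:
        n_val = max(1, int(round(train_cfg.validation_fraction * len(ids))))
        order = split_rng.permutation(len(ids))
        val_ids = [ids[i] for i in order[:n_val]]
        ids = [ids[i] for i in order[n_val:]]
        if not ids:
            raise TrainerError("validation split leaves no training sequences")

    n_pos = sum(ds[i][1].n_positive for i in ids)
    n_tot = sum(len(ds[i][1]) for i in ids)
    counts = ClassCounts(n_neg=max(n_tot - n_pos, 1), n_pos=max(n_pos, 1))

    backbone = Backbone(backbone_cfg, init_rng)
    centers = CenterBank(_tcl_feature_dim(backbone_cfg, loss_cfg), center_rng)
    opt = Adam(backbone.parameters(), lr=train_cfg.model_lr)

    log = TrainLog()
    best_auc, best_state, stale = -np.inf, None, 0
    for epoch in range(train_cfg.epochs):
        focal_sum = tcl_sum = total_sum = 0.0
        n_batches = 0
        for batch_ids in _epoch_batches(ids, train_cfg.batch_size, shuffle_rng):
            x, mask = batchify([embeddings[i] for i in batch_ids])
            labels = np.zeros(mask.shape, dtype=int)
            for row, rid in enumerate(batch_ids):
                track = ds[rid][1]
                labels[row, : len(track)] = track.labels

            backbone.zero_grad()
            centers.zero_grad()
            focal, tcl = _joint_loss_and_backward(
                backbone, centers, x, mask, labels, counts, loss_cfg, drop_rng
            )
            opt.step()
            if loss_cfg.lambda_ > 0.0:
                centers.sgd_step(loss_cfg.center_lr)

            focal_sum += focal
            tcl_sum += tcl
            total_sum += joint_loss(focal, tcl, loss_cfg.lambda_)
            n_batches += 1

        row = {
            "epoch": epoch,
            "focal": focal_sum / n_batches,
            "tcl": tcl_sum / n_batches,
            "total": total_sum / n_batches,
        }
        if val_ids:
            preds = predict_tracks(backbone, [embeddings[i] for i in val_ids])
            scores = np.concatenate([p.p_bind for p in preds])
            truth = np.concatenate([np.asarray(ds[i][1].labels) for i in val_ids])
            _, _, auc, aupr = roc_pr_curves(scores, truth)
            row["val_auc"], row["val_aupr"] = auc, aupr
            if train_cfg.early_stop_patience is not None:
                if auc > best_auc:
                    best_auc, stale = auc, 0
                    best_state = backbone.state_dict()
                    best_state["__centers__"] = centers.centers.copy()
                else:
                    stale += 1
        log.append(**row)
        if (
            train_cfg.early_stop_patience is not None
            and stale >= train_cfg.early_stop_patience
        ):
            break

    if best_state is not None:
        centers.centers[...] = best_state.pop("__centers__")
        backbone.load_state_dict(best_state)

    model = TrainedModel(backbone, centers, backbone_cfg, loss_cfg, train_cfg, counts)
    return model, log


def predict_tracks(
    backbone: Backbone, embeddings: Sequence[EmbeddingMatrix], batch_size: int = 32
) -> list[PredictionTrack]:
    """Eval-mode per-residue binding probabilities for each embedding."""
    out: list[PredictionTrack] = []
    for start in range(0, len(embeddings), batch_size):
        out.extend(backbone.predict_batch(embeddings[start : start + batch_size]))
    return out


def predict(
    model: TrainedModel, embeddings: Sequence[EmbeddingMatrix]
) -> list[PredictionTrack]:
    """Predict with a trained model, validating the embedding dimension."""
    for e in embeddings:
        if e.dim != model.backbone_cfg.in_dim:
            raise TrainerError(
                f"id {e.id!r}: embedding dim {e.dim} != model in_dim "
                f"{model.backbone_cfg.in_dim}"
            )
    return predict_tracks(model.backbone, embeddings)
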