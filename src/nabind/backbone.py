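"""Four-layer 1D-convolutional per-residue classifier.

Maps an L x D embedding matrix to L x 2 class probabilities.  Every layer uses
stride 1 and symmetric zero padding of (kernel-1)/2, so the output length
always equals the input length.  The first three layers are
conv -> batch-norm -> ReLU -> dropout; the last layer is a plain convolution
producing two logits per residue, followed by a softmax head.

Variable-length sequences are batched by zero-padding to a common length with
a boolean mask.  The mask contract: inputs are re-masked before every
convolution and batch-norm statistics are computed over real residues only,
so the content of padded positions can never influence a real residue's
output, the loss, or any gradient.

Implemented directly on numpy arrays with explicit forward/backward passes;
per-layer feature maps are retrievable from the forward result (used both for
triplet-center-loss feature selection and for embedding-space analyses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .embedding import EmbeddingMatrix


class BackboneError(ValueError):
    pass


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture of the per-residue classifier.

    ``layer_dims`` are the output channels of the four convolutions; the last
    must be 2 (binding / non-binding logits).  ``in_dim`` is the embedding
    dimension fed to layer 1 (1024 for the ProtBert encoder).
    """

    in_dim: int = 1024
    layer_dims: tuple[int, int, int, int] = (1024, 128, 64, 2)
    kernel_sizes: tuple[int, int, int, int] = (7, 5, 3, 3)
    dropout_rate: float = 0.3
    batchnorm: bool = True

    def __post_init__(self) -> None:
        if len(self.layer_dims) != 4 or len(self.kernel_sizes) != 4:
            raise BackboneError("exactly 4 layers are required")
        if self.layer_dims[-1] != 2:
            raise BackboneError("last layer must output 2 channels")
        if any(k <= 0 or k % 2 == 0 for k in self.kernel_sizes):
            raise BackboneError("kernel sizes must be odd positive integers")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise BackboneError("dropout_rate must be in [0, 1)")
        if self.in_dim <= 0:
            raise BackboneError("in_dim must be positive")

    def to_dict(self) -> dict:
        return {
            "in_dim": self.in_dim,
            "layer_dims": list(self.layer_dims),
            "kernel_sizes": list(self.kernel_sizes),
            "dropout_rate": self.dropout_rate,
            "batchnorm": self.batchnorm,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BackboneConfig":
        kwargs: dict = {}
        if "in_dim" in d:
            kwargs["in_dim"] = int(d["in_dim"])
        if "layer_dims" in d:
            kwargs["layer_dims"] = tuple(d["layer_dims"])
        if "kernel_sizes" in d:
            kwargs["kernel_sizes"] = tuple(d["kernel_sizes"])
        if "dropout_rate" in d:
            kwargs["dropout_rate"] = float(d["dropout_rate"])
        if "batchnorm" in d:
            kwargs["batchnorm"] = bool(d["batchnorm"])
        return cls(**kwargs)


@dataclass(frozen=True)
class PredictionTrack:
    """Per-residue binding probabilities for one sequence."""

    id: str
    p_bind: np.ndarray

    def __post_init__(self) -> None:
        p = self.p_bind
        if p.ndim != 1 or p.size == 0:
            raise BackboneError(f"{self.id!r}: p_bind must be a non-empty vector")
        if np.any(p < 0) or np.any(p > 1):
            raise BackboneError(f"{self.id!r}: probabilities outside [0, 1]")

    def calls(self, threshold: float = 0.5) -> np.ndarray:
        """Binary binding calls: residue i is called binding iff p_bind[i] > threshold.

        Strict comparison, so threshold 0 calls every residue binding and
        threshold 1 calls none (softmax probabilities can saturate to 1.0).
        """
        return (self.p_bind > threshold).astype(np.int8)

    def __len__(self) -> int:
        return len(self.p_bind)


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def batchify(
    embeddings: Sequence[EmbeddingMatrix | np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack variable-length embedding matrices into (B, Lmax, D) + mask.

    The mask has exactly sum(L_i) true entries; padded positions are zeros but
    the network never reads them (mask contract above).
    """
    mats = [e.values if isinstance(e, EmbeddingMatrix) else np.asarray(e) for e in embeddings]
    if not mats:
        raise BackboneError("cannot batch an empty list")
    dims = {m.shape[1] for m in mats}
    if len(dims) != 1:
        raise BackboneError(f"inconsistent embedding dims in batch: {sorted(dims)}")
    lmax = max(m.shape[0] for m in mats)
    x = np.zeros((len(mats), lmax, dims.pop()))
    mask = np.zeros((len(mats), lmax), dtype=bool)
    for i, m in enumerate(mats):
        x[i, : m.shape[0]] = m
        mask[i, : m.shape[0]] = True
    return x, mask


class _Conv1d:
    """Same-length 1-D convolution over (B, L, Cin) -> (B, L, Cout)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.kernel, self.c_in, self.c_out = kernel, c_in, c_out
        self.pad = (kernel - 1) // 2
        std = np.sqrt(2.0 / (kernel * c_in))
        self.w = Param(rng.standard_normal((kernel, c_in, c_out)) * std)
        self.b = Param(np.zeros(c_out))
        self._cols: np.ndarray | None = None
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, mask: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[2] != self.c_in:
            raise BackboneError(
                f"input has {x.shape[2]} channels, layer expects {self.c_in}"
            )
        xm = x * mask[:, :, None]
        xp = np.pad(xm, ((0, 0), (self.pad, self.pad), (0, 0)))
        # (B, L, Cin, k) -> (B, L, k*Cin)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            x.shape[0], x.shape[1], self.kernel * self.c_in
        )
        if train:
            self._cols, self._mask = cols, mask
        return cols @ self.w.value.reshape(-1, self.c_out) + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        cols, mask = self._cols, self._mask
        b, l = g.shape[0], g.shape[1]
        self.w.grad += (
            cols.reshape(-1, self.kernel * self.c_in).T @ g.reshape(-1, self.c_out)
        ).reshape(self.w.value.shape)
        self.b.grad += g.sum(axis=(0, 1))
        dcols = (g @ self.w.value.reshape(-1, self.c_out).T).reshape(
            b, l, self.kernel, self.c_in
        )
        dxp = np.zeros((b, l + 2 * self.pad, self.c_in))
        for j in range(self.kernel):
            dxp[:, j : j + l] += dcols[:, :, j]
        return dxp[:, self.pad : self.pad + l] * mask[:, :, None]

    def params(self, prefix: str) -> dict[str, Param]:
        return {f"{prefix}.w": self.w, f"{prefix}.b": self.b}


class _MaskedBatchNorm:
    """Per-channel batch norm whose statistics exclude padded positions."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self._cache = None

    def forward(self, x: np.ndarray, mask: np.ndarray, train: bool) -> np.ndarray:
        if train:
            m = mask[:, :, None]
            n = mask.sum()
            if n < 2:
                raise BackboneError("batch norm needs at least 2 real residues")
            mean = (x * m).sum(axis=(0, 1)) / n
            var = (((x - mean) * m) ** 2).sum(axis=(0, 1)) / n
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var, n = self.running_mean, self.running_var, None
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._cache = (xhat, inv_std, mask, n)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv_std, mask, n = self._cache
        m = mask[:, :, None]
        gm = g * m  # upstream grads at padded positions are already zero; be safe
        self.gamma.grad += (gm * xhat).sum(axis=(0, 1))
        self.beta.grad += gm.sum(axis=(0, 1))
        gx = gm * self.gamma.value
        sum_gx = gx.sum(axis=(0, 1))
        sum_gx_xhat = (gx * xhat).sum(axis=(0, 1))
        return (inv_std / n) * (n * gx - sum_gx - xhat * sum_gx_xhat) * m

    def params(self, prefix: str) -> dict[str, Param]:
        return {f"{prefix}.gamma": self.gamma, f"{prefix}.beta": self.beta}


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._pos = x > 0
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._pos


class _Dropout:
    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._keep = None
            return x
        if rng is None:
            raise BackboneError("dropout in train mode requires an rng")
        self._keep = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._keep

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._keep is None else g * self._keep


class _ConvBlock:
    """conv -> [batch-norm] -> ReLU -> dropout (hidden layers only)."""

    def __init__(self, c_in, c_out, kernel, dropout, batchnorm, final, rng):
        self.conv = _Conv1d(c_in, c_out, kernel, rng)
        self.final = final
        self.bn = _MaskedBatchNorm(c_out) if (batchnorm and not final) else None
        self.relu = None if final else _ReLU()
        self.drop = None if final else _Dropout(dropout)

    def forward(self, x, mask, train, rng):
        h = self.conv.forward(x, mask, train)
        if self.bn is not None:
            h = self.bn.forward(h, mask, train)
        if self.relu is not None:
            h = self.relu.forward(h, train)
        if self.drop is not None:
            h = self.drop.forward(h, train, rng)
        return h

    def backward(self, g):
        if self.drop is not None:
            g = self.drop.backward(g)
        if self.relu is not None:
            g = self.relu.backward(g)
        if self.bn is not None:
            g = self.bn.backward(g)
        return self.conv.backward(g)

    def params(self, prefix: str) -> dict[str, Param]:
        out = self.conv.params(f"{prefix}.conv")
        if self.bn is not None:
            out.update(self.bn.params(f"{prefix}.bn"))
        return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class ForwardResult:
    """Per-layer feature maps plus the softmax output of one forward pass.

    ``features[i]`` is the output of block i (post-activation for hidden
    blocks, raw logits for the final block); all have shape (B, L, C_i).
    """

    features: list[np.ndarray]
    logits: np.ndarray
    probs: np.ndarray
    mask: np.ndarray


class Backbone:
    """The trainable classifier: four masked conv blocks plus a softmax head."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        self.cfg = cfg
        dims = (cfg.in_dim, *cfg.layer_dims)
        self.blocks = [
            _ConvBlock(
                dims[i],
                dims[i + 1],
                cfg.kernel_sizes[i],
                cfg.dropout_rate,
                cfg.batchnorm,
                final=(i == 3),
                rng=rng,
            )
            for i in range(4)
        ]

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> dict[str, Param]:
        out: dict[str, Param] = {}
        for i, blk in enumerate(self.blocks):
            out.update(blk.params(f"block{i}"))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.value.copy() for k, p in self.parameters().items()}
        for i, blk in enumerate(self.blocks):
            if blk.bn is not None:
                state[f"block{i}.bn.running_mean"] = blk.bn.running_mean.copy()
                state[f"block{i}.bn.running_var"] = blk.bn.running_var.copy()
        return state

    def load_state_dict(self, state: Mapping[str, np.ndarray]) -> None:
        params = self.parameters()
        for k, p in params.items():
            p.value[...] = state[k]
        for i, blk in enumerate(self.blocks):
            if blk.bn is not None:
                blk.bn.running_mean[...] = state[f"block{i}.bn.running_mean"]
                blk.bn.running_var[...] = state[f"block{i}.bn.running_var"]

    # -- forward / backward -------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        mask: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> ForwardResult:
        if x.ndim != 3 or x.shape[2] != self.cfg.in_dim:
            raise BackboneError(
                f"expected input (B, L, {self.cfg.in_dim}), got shape {x.shape}"
            )
        h = x
        features = []
        for blk in self.blocks:
            h = blk.forward(h, mask, train, rng)
            features.append(h)
        logits = features[-1]
        return ForwardResult(features, logits, softmax(logits), mask)

    def backward(
        self,
        dlogits: np.ndarray,
        feature_grads: Mapping[int, np.ndarray] | None = None,
    ) -> None:
        """Backpropagate a logit gradient, optionally injecting extra
        gradients at intermediate feature maps (triplet-center loss)."""
        g = dlogits
        for i in reversed(range(4)):
            if feature_grads and i in feature_grads and i != 3:
                g = g + feature_grads[i]
            g = self.blocks[i].backward(g)
        # gradient stops here: embeddings are frozen inputs, never updated

    def predict_batch(self, embeddings: Sequence[EmbeddingMatrix]) -> list[PredictionTrack]:
        """Eval-mode binding probabilities for a list of embedding matrices."""
        x, mask = batchify(embeddings)
        res = self.forward(x, mask, train=False)
        return [
            PredictionTrack(e.id, res.probs[i, : e.length, 1].copy())
            for i, e in enumerate(embeddings)
        ]
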