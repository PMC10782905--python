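"""Per-residue embedding matrices from protein sequences.

Two embedders share one contract (L rows out for an L-residue sequence, all
entries finite):

* :func:`embed_protbert` — an adapter around a frozen pre-trained protein
  language model (1024-dim per-residue features).  The encoder is used purely
  as a feature extractor; its parameters receive no gradient downstream.
* :func:`embed_fallback` — a deterministic, download-free stand-in: each
  residue's row is a fixed seeded random projection of the one-hot encodings
  of the residues in a centered window.  It gives the classifier local-context
  structure to learn from at desk scale.

Embeddings are computed once and cached in a keyed ``.npz`` container
(one float32 array per sequence id plus a JSON metadata entry).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .seqio import ALPHABET, ProteinRecord

CACHE_VERSION = 1
_META_KEY = "__nabind_meta__"
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: per-residue feature dimension of the ProtBert encoder
PROTBERT_DIM = 1024


class EmbedderUnavailableError(RuntimeError):
    """The requested external encoder cannot be loaded in this environment."""


class EmbeddingError(ValueError):
    """Invalid embedding input, cache or dimension mismatch."""


@dataclass(frozen=True)
class EmbedderSpec:
    """Configuration of an embedder.

    ``seed`` and ``window`` apply to the fallback embedder only; ``window``
    must be odd so the context window is centered on the residue.
    """

    name: str = "fallback"
    dim: int = 16
    deterministic: bool = True
    seed: int = 0
    window: int = 5

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise EmbeddingError("embedding dim must be positive")
        if self.window <= 0 or self.window % 2 == 0:
            raise EmbeddingError("window must be an odd positive integer")


@dataclass(frozen=True)
class EmbeddingMatrix:
    """An L x D matrix of per-residue features for one sequence."""

    id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2:
            raise EmbeddingError(f"{self.id!r}: embedding must be 2-D, got shape {v.shape}")
        if v.shape[0] < 1:
            raise EmbeddingError(f"{self.id!r}: embedding has no rows")
        if not np.all(np.isfinite(v)):
            raise EmbeddingError(f"{self.id!r}: embedding contains non-finite values")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# fallback embedder: windowed one-hot random projection
# ---------------------------------------------------------------------------

def _projection_matrix(spec: EmbedderSpec) -> np.ndarray:
    # Fixed given (seed, window, dim): rows of the returned (window, 21, dim)
    # tensor are the projection of "residue a at window offset w".
    rng = np.random.default_rng(spec.seed)
    n_in = spec.window * len(ALPHABET)
    proj = rng.standard_normal((n_in, spec.dim)) / np.sqrt(n_in)
    return proj.reshape(spec.window, len(ALPHABET), spec.dim)


def embed_fallback(rec: ProteinRecord, spec: EmbedderSpec) -> EmbeddingMatrix:
    """Deterministic windowed one-hot random-projection embedding.

    Row *i* is the sum of projection rows for the residues at window offsets
    around position *i*; positions beyond the sequence ends contribute zero,
    exactly as a zero-padded one-hot window would.
    """
    if not spec.deterministic:
        raise EmbeddingError("fallback embedder requires deterministic=True")
    proj = _projection_matrix(spec)
    codes = np.array([_AA_INDEX[ch] for ch in rec.sequence], dtype=np.intp)
    L, half = len(codes), spec.window // 2
    out = np.zeros((L, spec.dim))
    for w in range(spec.window):
        offset = w - half
        lo, hi = max(0, -offset), min(L, L - offset)
        if lo < hi:
            out[lo:hi] += proj[w, codes[lo + offset:hi + offset]]
    return EmbeddingMatrix(rec.id, out)


# ---------------------------------------------------------------------------
# ProtBert adapter (frozen external encoder)
# ---------------------------------------------------------------------------

def protbert_preprocess(sequence: str) -> str:
    """Space-separate residues, uppercase, rare residues (B, Z, U, O, J) -> 'X'."""
    seq = sequence.upper()
    return " ".join(ch if ch in _AA_INDEX else "X" for ch in seq)


def chunk_spans(length: int, max_len: int, overlap: int) -> list[tuple[int, int, int, int]]:
    """Plan overlapping chunks for sequences beyond the encoder context.

    Returns ``(start, stop, take_from, take_to)`` per chunk: the chunk covers
    residues ``[start, stop)`` and contributes rows ``[take_from, take_to)``
    of itself to the stitched output, so that adjacent chunks split their
    overlap at its midpoint and every residue is covered exactly once.
    """
    if max_len <= overlap:
        raise EmbeddingError("max_len must exceed overlap")
    if length <= max_len:
        return [(0, length, 0, length)]
    spans: list[tuple[int, int]] = []
    start = 0
    while True:
        stop = min(start + max_len, length)
        spans.append((start, stop))
        if stop == length:
            break
        start = stop - overlap
    out = []
    for i, (start, stop) in enumerate(spans):
        take_from = 0 if i == 0 else (spans[i - 1][1] - start + 1) // 2
        take_to = stop - start if i == len(spans) - 1 else (
            (spans[i + 1][0] - start) + ((stop - spans[i + 1][0]) + 1) // 2
        )
        out.append((start, stop, take_from, take_to))
    return out


def embed_protbert(
    rec: ProteinRecord,
    model_name: str = "Rostlab/prot_bert",
    max_len: int = 1022,
    overlap: int = 64,
) -> EmbeddingMatrix:
    """Embed a sequence with a frozen ProtBert encoder (1024-dim per residue).

    The begin/end special-token rows are stripped so the output has exactly L
    rows.  Sequences beyond the encoder context are chunked with overlap and
    stitched at overlap midpoints.  Raises :class:`EmbedderUnavailableError`
    with a pointer to :func:`embed_fallback` when the encoder stack is not
    installed locally.
    """
    if len(rec.sequence) == 0:
        raise EmbeddingError("cannot embed an empty sequence")
    try:
        import torch  # noqa: F401
        from transformers import BertModel, BertTokenizer
    except ImportError as exc:
        raise EmbedderUnavailableError(
            "the ProtBert encoder requires the 'torch' and 'transformers' "
            "packages, which are not installed; use the deterministic "
            "fallback embedder (nabind.embedding.embed_fallback) instead"
        ) from exc

    import torch

    tokenizer = BertTokenizer.from_pretrained(model_name, do_lower_case=False)
    model = BertModel.from_pretrained(model_name)
    model.eval()

    L = len(rec.sequence)
    out = np.empty((L, PROTBERT_DIM), dtype=np.float32)
    for start, stop, take_from, take_to in chunk_spans(L, max_len, overlap):
        chunk = protbert_preprocess(rec.sequence[start:stop])
        with torch.no_grad():
            inputs = tokenizer(chunk, return_tensors="pt")
            hidden = model(**inputs).last_hidden_state[0].numpy()
        n_res = stop - start
        rows = hidden[1:1 + n_res]  # strip [CLS] and [SEP]
        if rows.shape[0] != n_res:
            raise EmbeddingError(
                f"{rec.id!r}: encoder returned {rows.shape[0]} residue rows "
                f"for a {n_res}-residue chunk"
            )
        out[start + take_from:start + take_to] = rows[take_from:take_to]
    return EmbeddingMatrix(rec.id, out.astype(np.float64))


# ---------------------------------------------------------------------------
# cache
# ---------------------------------------------------------------------------

def save_embeddings(
    embs: Iterable[EmbeddingMatrix],
    path: str | Path,
    *,
    meta: Mapping[str, object] | None = None,
) -> Path:
    """Write embedding matrices to a keyed ``.npz`` cache (round-trip exact)."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    dim = None
    for emb in embs:
        if emb.id in arrays:
            raise EmbeddingError(f"duplicate id in cache: {emb.id!r}")
        if dim is None:
            dim = emb.dim
        elif emb.dim != dim:
            raise EmbeddingError(
                f"{emb.id!r}: dim {emb.dim} differs from cache dim {dim}"
            )
        arrays[emb.id] = emb.values
    if not arrays:
        raise EmbeddingError("no embeddings to cache")
    header = {"version": CACHE_VERSION, "dim": dim}
    if meta:
        header.update(meta)
    np.savez(path, **arrays, **{_META_KEY: np.array(json.dumps(header))})
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def cache_embeddings(
    records: Iterable[ProteinRecord],
    embedder,
    path: str | Path,
    *,
    meta: Mapping[str, object] | None = None,
) -> Path:
    """Embed every record and write a keyed ``.npz`` cache.

    ``embedder`` is any callable mapping a :class:`ProteinRecord` to an
    :class:`EmbeddingMatrix` (e.g. ``partial(embed_fallback, spec=spec)``).
    """
    return save_embeddings((embedder(rec) for rec in records), path, meta=meta)


def load_embeddings(
    path: str | Path, expected_dim: int | None = None
) -> dict[str, EmbeddingMatrix]:
    """Load a cache written by :func:`cache_embeddings`; round-trip is exact."""
    with np.load(path) as data:
        keys = [k for k in data.files if k != _META_KEY]
        if _META_KEY in data.files:
            header = json.loads(str(data[_META_KEY]))
            dim = header.get("dim")
            if expected_dim is not None and dim is not None and dim != expected_dim:
                raise EmbeddingError(
                    f"cache dim {dim} does not match expected dim {expected_dim}"
                )
        out = {k: EmbeddingMatrix(k, data[k]) for k in keys}
    if expected_dim is not None:
        for emb in out.values():
            if emb.dim != expected_dim:
                raise EmbeddingError(
                    f"{emb.id!r}: dim {emb.dim} does not match expected {expected_dim}"
                )
    return out
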