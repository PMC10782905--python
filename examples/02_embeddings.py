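"""Per-residue embeddings and the .npz cache.

The classifier consumes one fixed-length vector per residue.  Two embedders
are provided:

* `embed_protbert` wraps a frozen pre-trained protein language model
  (requires the optional `torch`/`transformers` extra; long sequences are
  chunked with overlap and stitched).
* `embed_fallback` is a dependency-free deterministic embedder: a seeded
  random projection of the windowed one-hot encoding.  It preserves the
  contract (L rows, fixed dim, locality) and is used throughout the tests
  and the synthetic benchmark.

Embeddings are cached in a keyed .npz file so training never recomputes them.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from nabind import EmbedderSpec, ProteinRecord
from nabind.embedding import cache_embeddings, embed_fallback, load_embeddings

records = [ProteinRecord("protA", "MKRYACDEFGHIKLMN"), ProteinRecord("protB", "GGSTKKRRYAV")]
spec = EmbedderSpec(name="fallback", dim=16, seed=0, window=5)

emb = embed_fallback(records[0], spec)
print(f"{emb.id}: {emb.values.shape[0]} residues x {emb.values.shape[1]} dims")
print(f"first residue vector starts with {emb.values[0, :3].round(3)}")

with TemporaryDirectory() as tmp:
    cache = Path(tmp) / "embeddings.npz"
    cache_embeddings(records, lambda r: embed_fallback(r, spec), cache)
    loaded = load_embeddings(cache, expected_dim=16)
    print(f"cached and reloaded {len(loaded)} embeddings bitwise-exactly:",
          (loaded["protA"].values == emb.values).all())
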