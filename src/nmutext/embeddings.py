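"""Pluggable token/document embedding providers.

The pipeline consumes dense token vectors through a small provider contract so
that any pre-trained contextual model can be dropped in. Two context-free
providers ship with the package: a keyed-hash provider (deterministic unit
vectors, no training, no vocabulary) and a seeded lookup table with an UNK row.
Document vectors are mean-pooled token vectors.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "EmbeddingProvider",
    "DocEmbedding",
    "hash_provider",
    "lookup_provider",
    "embed_document",
    "save_table",
]

UNK_TOKEN = "UNK"


@dataclass(frozen=True)
class EmbeddingProvider:
    """Maps a token list to an (n_tokens, dim) real matrix.

    ``embed_tokens`` receives the whole token sequence so contextual providers
    fit the contract; the shipped providers are context-free.
    """

    name: str
    dim: int
    embed_tokens: Callable[[Sequence[str]], np.ndarray]
    deterministic: bool = True

    def __call__(self, tokens: Sequence[str]) -> np.ndarray:
        out = np.asarray(self.embed_tokens(tokens), dtype=float)
        if out.shape != (len(tokens), self.dim):
            raise ValueError(
                f"provider {self.name!r} returned shape {out.shape}, "
                f"expected {(len(tokens), self.dim)}"
            )
        return out


@dataclass(frozen=True)
class DocEmbedding:
    record_id: str
    vector: np.ndarray


def _token_vector(token: str, dim: int, seed: int) -> np.ndarray:
    digest = hashlib.sha256(f"{seed}\x00{token}".encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
    v = rng.standard_normal(dim)
    norm = np.linalg.norm(v)
    while norm == 0.0:  # astronomically unlikely; redraw for safety
        v = rng.standard_normal(dim)
        norm = np.linalg.norm(v)
    return v / norm


def hash_provider(dim: int, seed: int = 0) -> EmbeddingProvider:
    """Deterministic context-free provider: unit vectors keyed by (token, seed)."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    cache: dict[str, np.ndarray] = {}

    def embed(tokens: Sequence[str]) -> np.ndarray:
        out = np.empty((len(tokens), dim))
        for i, tok in enumerate(tokens):
            vec = cache.get(tok)
            if vec is None:
                vec = _token_vector(tok, dim, seed)
                cache[tok] = vec
            out[i] = vec
        return out

    return EmbeddingProvider(name=f"hash-{dim}d", dim=dim, embed_tokens=embed)


def lookup_provider(
    vocabulary: Mapping[str, int], dim: int, seed: int = 0
) -> EmbeddingProvider:
    """Trainable lookup table initialized uniform(-0.1, 0.1); OOV tokens share an UNK row.

    The table is exposed as the ``table`` attribute on the returned provider so a
    training loop may update it in place.
    """
    if not vocabulary:
        raise ValueError("vocabulary must be non-empty")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(seed)
    index = dict(vocabulary)
    if UNK_TOKEN not in index:
        index[UNK_TOKEN] = len(index)
    table = rng.uniform(-0.1, 0.1, size=(len(index), dim))
    unk_row = index[UNK_TOKEN]

    def embed(tokens: Sequence[str]) -> np.ndarray:
        rows = [index.get(tok, unk_row) for tok in tokens]
        return table[rows]

    provider = EmbeddingProvider(name=f"lookup-{dim}d", dim=dim, embed_tokens=embed)
    object.__setattr__(provider, "table", table)
    object.__setattr__(provider, "index", index)
    return provider


def embed_document(provider: EmbeddingProvider, tokens: Sequence[str], record_id: str = "") -> DocEmbedding:
    """Mean-pool token vectors into one document vector."""
    if not tokens:
        raise ValueError("embed_document requires a non-empty token list")
    vectors = provider(tokens)
    return DocEmbedding(record_id=record_id, vector=vectors.mean(axis=0))


def save_table(provider: EmbeddingProvider, path: str | Path) -> None:
    """Serialize a lookup provider's table: header line then token<TAB>values rows."""
    table = getattr(provider, "table", None)
    index = getattr(provider, "index", None)
    if table is None or index is None:
        raise ValueError("provider has no serializable table")
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{provider.name}\t{provider.dim}\n")
        for tok, row in index.items():
            values = "\t".join(repr(x) for x in table[row])
            fh.write(f"{tok}\t{values}\n")
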