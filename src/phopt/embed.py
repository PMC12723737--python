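"""Per-residue embedding backends.

The network consumes a real matrix ``r`` of shape (dim, L) with one column of
features per residue. Two backends produce it:

* :class:`FixtureEmbedder` — a deterministic dictionary embedder: every
  residue letter maps to a fixed seeded random vector, so column ``i`` depends
  only on ``sequence[i]`` and the seed. This is the default and what the test
  suite uses; it needs no downloads.
* :class:`PLMEmbedder` — an adapter around the ESM-2 protein language model
  (esm2_t6_8M_UR50D, dim=320, final hidden layer with begin/end special tokens
  stripped so the output length is exactly L). It requires ``torch`` and
  ``fair-esm`` with downloaded weights and raises :class:`CapabilityError`
  when they are absent.

Ambiguity codes (X, B, Z, U, O) map to a single shared "unknown" vector in the
fixture backend; the adapter passes them through to ESM-2's own tokenizer.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from .exceptions import CapabilityError, ContractError
from .io import AMBIGUOUS_AA, STANDARD_AA, ProteinRecord

CACHE_FORMAT_VERSION = "v1"


class Embedder(Protocol):
    """Anything that turns a sequence into a (dim, L) feature matrix."""

    dim: int

    def embed(self, sequence: str) -> np.ndarray: ...


class FixtureEmbedder:
    """Deterministic dictionary embedder: letter -> frozen seeded vector.

    Pure function of (seed, sequence): identical sequences give bit-identical
    matrices, and permuting residues permutes columns identically.
    """

    backend = "fixture"

    def __init__(self, dim: int = 320, seed: int = 0):
        if dim <= 0:
            raise ContractError("embedding dim must be positive")
        self.dim = dim
        self.seed = seed
        rng = np.random.default_rng(seed)
        # one row per standard letter, plus a shared unknown vector (last row)
        table = rng.standard_normal((len(STANDARD_AA) + 1, dim))
        self._index = {aa: i for i, aa in enumerate(STANDARD_AA)}
        unknown = len(STANDARD_AA)
        for aa in AMBIGUOUS_AA:
            self._index[aa] = unknown
        self._table = table

    def embed(self, sequence: str) -> np.ndarray:
        if len(sequence) < 1:
            raise ContractError("cannot embed an empty sequence")
        idx = np.fromiter((self._index[aa] for aa in sequence.upper()),
                          dtype=np.int64, count=len(sequence))
        return self._table[idx].T.copy()  # (dim, L)


class PLMEmbedder:
    """ESM-2 adapter (esm2_t6_8M_UR50D by default).

    Uses the final hidden layer's per-residue representations and strips the
    begin/end special tokens so the output has exactly one column per residue.
    """

    backend = "plm_adapter"

    def __init__(self, model_name: str = "esm2_t6_8M_UR50D"):
        try:
            import esm  # type: ignore
            import torch  # noqa: F401
        except ImportError as exc:
            raise CapabilityError(
                "the protein-language-model backend requires 'torch' and "
                "'fair-esm' with downloaded weights; use FixtureEmbedder "
                "instead (the deterministic test backend)"
            ) from exc
        self._model, self._alphabet = getattr(
            esm.pretrained, model_name)()
        self._model.eval()
        self._n_layers = self._model.num_layers
        self.dim = self._model.embed_dim

    def embed(self, sequence: str) -> np.ndarray:
        import torch

        converter = self._alphabet.get_batch_converter()
        _, _, tokens = converter([("query", sequence)])
        with torch.no_grad():
            out = self._model(tokens, repr_layers=[self._n_layers])
        rep = out["representations"][self._n_layers][0]
        # strip BOS/EOS so length equals L
        return rep[1:len(sequence) + 1].numpy().T


def embed_sequence(embedder: Embedder, record: ProteinRecord | str) -> np.ndarray:
    """Embed one sequence to a (dim, L) matrix with no non-finite entries."""
    seq = getattr(record, "sequence", record)
    mat = embedder.embed(seq)
    if mat.shape != (embedder.dim, len(seq)):
        raise ContractError(
            f"embedder returned shape {mat.shape}, "
            f"expected {(embedder.dim, len(seq))}"
        )
    if not np.all(np.isfinite(mat)):
        raise ContractError("embedding contains non-finite entries")
    return mat


def embed_batch(embedder: Embedder,
                records: Sequence[ProteinRecord | str],
                pad_to: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Embed a batch, zero-padding to a common length.

    Returns ``(values, mask)`` with ``values`` of shape (B, dim, Lmax) and a
    boolean ``mask`` of shape (B, Lmax) marking real (unpadded) positions.
    Padded columns are zero; the model masks them so they never influence
    predictions.
    """
    if not records:
        raise ContractError("embed_batch requires a non-empty batch")
    seqs = [getattr(r, "sequence", r) for r in records]
    lengths = [len(s) for s in seqs]
    L = max(lengths) if pad_to is None else pad_to
    if L < max(lengths):
        raise ContractError(f"pad_to={pad_to} shorter than longest sequence")
    B = len(seqs)
    values = np.zeros((B, embedder.dim, L))
    mask = np.zeros((B, L), dtype=bool)
    for i, seq in enumerate(seqs):
        values[i, :, :len(seq)] = embed_sequence(embedder, seq)
        mask[i, :len(seq)] = True
    return values, mask


class EmbeddingCache:
    """Optional on-disk cache of embedding matrices.

    Keys are (backend, dim, seed, sequence-hash); the layout is versioned so a
    format change invalidates old entries rather than silently misreading them.
    """

    def __init__(self, directory: str | Path):
        self.root = Path(directory) / CACHE_FORMAT_VERSION
        self.root.mkdir(parents=True, exist_ok=True)

    def _key(self, embedder: Embedder, sequence: str) -> Path:
        seed = getattr(embedder, "seed", "")
        h = hashlib.sha256(sequence.encode()).hexdigest()[:32]
        backend = getattr(embedder, "backend", type(embedder).__name__)
        return self.root / f"{backend}-{embedder.dim}-{seed}-{h}.npy"

    def embed(self, embedder: Embedder, sequence: str) -> np.ndarray:
        path = self._key(embedder, sequence)
        if path.exists():
            return np.load(path)
        mat = embed_sequence(embedder, sequence)
        np.save(path, mat)
        return mat
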