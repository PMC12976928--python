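"""Residue-level embedding storage with a precompute-and-cache contract.

Unique amino-acid sequences are embedded once by a pluggable
:class:`EmbeddingProvider` (a protein language model, a one-hot encoder, or
the synthetic generator) and written to an HDF5 store keyed by the sequence
string. Batches for the model are then assembled by lookup, never by
re-embedding, so large runs cost one provider pass per unique sequence.

Every block is an N×d matrix whose rows beyond the sequence length are
exactly zero; masks carry the valid lengths downstream.
"""

from __future__ import annotations

import abc
import datetime
from dataclasses import dataclass
from typing import Iterable, Sequence

import h5py
import numpy as np

from .errors import StoreLookupError, TruncationError


@dataclass(frozen=True)
class EmbeddingBlock:
    """An N×d residue-embedding matrix with its valid length and sequence."""

    matrix: np.ndarray
    valid_length: int
    sequence: str

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2:
            raise ValueError("embedding matrix must be 2-D")
        if not 0 <= self.valid_length <= m.shape[0]:
            raise ValueError("valid_length out of range")
        if self.valid_length != len(self.sequence):
            raise ValueError("valid_length must equal len(sequence)")

    @property
    def mask(self) -> np.ndarray:
        """1.0 at valid residue rows, 0.0 at padding."""
        m = np.zeros(self.matrix.shape[0])
        m[: self.valid_length] = 1.0
        return m


class EmbeddingProvider(abc.ABC):
    """Produces a deterministic residue-level embedding for any sequence."""

    #: embedding dimension d
    dimension: int
    #: padded maximum sequence length N
    max_length: int
    name: str = "provider"

    @abc.abstractmethod
    def embed(self, sequence: str) -> EmbeddingBlock:
        """Embed one sequence into an N×d block (padding rows zero)."""

    def _pad(self, rows: np.ndarray, sequence: str) -> EmbeddingBlock:
        L = len(sequence)
        if L > self.max_length:
            raise TruncationError(
                f"sequence of length {L} exceeds max_length {self.max_length}: "
                f"{sequence!r}")
        block = np.zeros((self.max_length, self.dimension))
        block[:L] = rows
        return EmbeddingBlock(block, L, sequence)


class OneHotProvider(EmbeddingProvider):
    """One-hot residue encoding; a dependency-free baseline provider."""

    _ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
    name = "onehot"

    def __init__(self, max_length: int = 25):
        self.dimension = len(self._ALPHABET)
        self.max_length = max_length
        self._index = {aa: i for i, aa in enumerate(self._ALPHABET)}

    def embed(self, sequence: str) -> EmbeddingBlock:
        rows = np.zeros((len(sequence), self.dimension))
        for i, aa in enumerate(sequence):
            rows[i, self._index[aa]] = 1.0
        return self._pad(rows, sequence)


def build_store(sequences: Iterable[str], provider: EmbeddingProvider,
                path) -> "EmbeddingStore":
    """Embed each unique sequence once and write an HDF5 store at ``path``."""
    unique = sorted(set(sequences))
    with h5py.File(path, "w") as f:
        f.attrs["provider"] = provider.name
        f.attrs["d"] = provider.dimension
        f.attrs["N"] = provider.max_length
        f.attrs["created"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
        for seq in unique:
            block = provider.embed(seq)  # raises TruncationError when too long
            ds = f.create_dataset(seq, data=block.matrix)
            ds.attrs["valid_length"] = block.valid_length
    return EmbeddingStore(path)


class EmbeddingStore:
    """Read-side handle over a store file; caches blocks in memory."""

    def __init__(self, path):
        self.path = path
        with h5py.File(path, "r") as f:
            self.dimension = int(f.attrs["d"])
            self.max_length = int(f.attrs["N"])
            self.provider_name = str(f.attrs["provider"])
            self._keys = set(f.keys())
        self._cache: dict[str, EmbeddingBlock] = {}

    def __contains__(self, sequence: str) -> bool:
        return sequence in self._keys

    def __len__(self) -> int:
        return len(self._keys)

    def keys(self):
        return sorted(self._keys)

    def get(self, sequence: str) -> EmbeddingBlock:
        if sequence in self._cache:
            return self._cache[sequence]
        if sequence not in self._keys:
            raise StoreLookupError(
                f"sequence {sequence!r} not present in store {self.path}")
        with h5py.File(self.path, "r") as f:
            ds = f[sequence]
            block = EmbeddingBlock(np.asarray(ds, dtype=np.float64),
                                   int(ds.attrs["valid_length"]), sequence)
        self._cache[sequence] = block
        return block


@dataclass
class TriadBatch:
    """Batched embeddings for a list of records, aligned row-for-row."""

    cdr3a: np.ndarray     # (B, N, d)
    cdr3b: np.ndarray     # (B, N, d)
    peptide: np.ndarray   # (B, N, d)
    mask_a: np.ndarray    # (B, N)
    mask_b: np.ndarray
    mask_e: np.ndarray
    labels: np.ndarray    # (B,)

    def __len__(self) -> int:
        return self.cdr3a.shape[0]


def assemble_batch(records: Sequence, store: EmbeddingStore) -> TriadBatch:
    """Look up and stack the three embedding blocks for each record.

    Record *i* maps to row *i* of each batched array; masks mark the valid
    residue rows. Raises :class:`StoreLookupError` naming the first missing
    sequence.
    """
    B, N, d = len(records), store.max_length, store.dimension
    out = {k: np.zeros((B, N, d)) for k in ("cdr3a", "cdr3b", "peptide")}
    masks = {k: np.zeros((B, N)) for k in ("cdr3a", "cdr3b", "peptide")}
    labels = np.zeros(B)
    for i, rec in enumerate(records):
        for key, seq in (("cdr3a", rec.cdr3a), ("cdr3b", rec.cdr3b),
                         ("peptide", rec.peptide)):
            block = store.get(seq)
            out[key][i] = block.matrix
            masks[key][i] = block.mask
        labels[i] = rec.label
    return TriadBatch(cdr3a=out["cdr3a"], cdr3b=out["cdr3b"],
                      peptide=out["peptide"], mask_a=masks["cdr3a"],
                      mask_b=masks["cdr3b"], mask_e=masks["peptide"],
                      labels=labels)
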