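"""Sequence-modality embeddings behind a uniform 640-dim interface.

Two embedders ship: a deterministic composition/2-mer embedder used by the
test suite and the pipeline default, and an optional adapter for a frozen
pretrained protein language model (640-dim hidden width).  The downstream
pipeline is embedder-agnostic: anything producing a fixed 640-vector per
sequence plugs in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .fixtures import AMINO_ACIDS

__all__ = ["EMBED_DIM", "SequenceEmbedder", "toy_embed", "toy_embedder",
           "plm_embed", "read_fasta", "PLMUnavailableError"]

EMBED_DIM = 640

_ALPHABET = AMINO_ACIDS + "X"  # 21 classes; index 20 = unknown


class PLMUnavailableError(RuntimeError):
    """No local language-model checkpoint; use the toy embedder instead."""


@dataclass(frozen=True)
class SequenceEmbedder:
    """Named embedding function with a fixed output dimension."""

    name: str
    dim: int
    fn: Callable[[str], np.ndarray]

    def embed(self, sequence: str) -> np.ndarray:
        v = self.fn(sequence)
        if v.shape != (self.dim,):
            raise ValueError(f"embedder {self.name} returned shape {v.shape}")
        return v


def _index(ch: str) -> int:
    i = AMINO_ACIDS.find(ch)
    return i if i >= 0 else 20


def toy_embed(sequence: str) -> np.ndarray:
    """Deterministic 640-vector: 21 composition + 441 2-mer frequencies + zeros.

    The composition block is the per-class frequency over the sequence; the
    2-mer block counts adjacent residue pairs (row-major 21x21), normalized
    by the number of 2-mers.  Sensitive to residue order through the 2-mers.
    """
    if not sequence:
        raise ValueError("sequence must be nonempty")
    comp = np.zeros(21)
    for ch in sequence:
        comp[_index(ch)] += 1.0
    comp /= len(sequence)
    kmer = np.zeros((21, 21))
    for a, b in zip(sequence, sequence[1:]):
        kmer[_index(a), _index(b)] += 1.0
    if len(sequence) > 1:
        kmer /= len(sequence) - 1
    v = np.concatenate([comp, kmer.ravel()])
    out = np.zeros(EMBED_DIM)
    out[: min(len(v), EMBED_DIM)] = v[:EMBED_DIM]
    return out


toy_embedder = SequenceEmbedder(name="toy-composition-2mer", dim=EMBED_DIM, fn=toy_embed)


def plm_embed(sequence: str, model_handle=None) -> np.ndarray:
    """Mean-pooled last-layer hidden states of a frozen 640-dim language model.

    ``model_handle`` must expose ``last_hidden_states(sequence) -> (L, 640)``
    over residue positions (special tokens already dropped).  Without a
    handle a :class:`PLMUnavailableError` is raised — the toy embedder covers
    every offline use.
    """
    if not sequence:
        raise ValueError("sequence must be nonempty")
    if model_handle is None:
        raise PLMUnavailableError(
            "no protein language model checkpoint is available; "
            "use protfuse.sequence_embedding.toy_embedder instead"
        )
    hidden = np.asarray(model_handle.last_hidden_states(sequence), dtype=float)
    if hidden.ndim != 2 or hidden.shape[1] != EMBED_DIM:
        raise ValueError(f"expected (L, {EMBED_DIM}) hidden states, got {hidden.shape}")
    return hidden.mean(axis=0)


def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by record id, for tasks supplying FASTA directly."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
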