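"""Deterministic synthetic structures and task tables.

Every stage of the pipeline is testable offline: :func:`make_helix` builds a
protein whose CA trace follows an ideal alpha-helix (rise 1.5 A/residue,
100 degrees/residue, radius 2.3 A — textbook helix geometry, used here as a
synthetic stand-in, not a biological claim) decorated with 1-4 dummy
side-chain atoms per residue, and :func:`make_affinity_task` emits a
protein-ligand CSV whose labels are a seeded smooth function of sequence
composition and ligand identity, so a regression head has learnable signal.

All outputs are pure functions of their seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .structures import Atom, ProteinStructure, three_to_one

__all__ = [
    "FixtureSpec",
    "AMINO_ACIDS",
    "BUILTIN_SMILES",
    "make_helix",
    "make_dataset",
    "make_affinity_task",
    "affinity_label",
    "make_shared_factor_triples",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# ten hand-written, chemically simple ligands
BUILTIN_SMILES = (
    "CCO",                  # ethanol
    "CC(=O)O",              # acetic acid
    "c1ccccc1",             # benzene
    "CC(=O)Nc1ccc(O)cc1",   # paracetamol
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",  # caffeine
    "C1CCCCC1",             # cyclohexane
    "NCCc1ccc(O)c(O)c1",    # dopamine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",    # ibuprofen
    "OC(=O)c1ccccc1O",      # salicylic acid
    "CSCC[C@H](N)C(=O)O",   # methionine
)

HELIX_RISE = 1.5     # Angstrom per residue
HELIX_TURN = 100.0   # degrees per residue
HELIX_RADIUS = 2.3   # Angstrom


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic dataset of helical structures."""

    n_structures: int = 60
    residues_range: tuple[int, int] = (30, 60)
    noise_sd: float = 0.3  # Angstrom; breaks distance ties in KNN graphs
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.residues_range
        if lo < 2 or hi < lo:
            raise ValueError("residues_range must satisfy 2 <= min <= max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_structures < 1:
            raise ValueError("n_structures must be >= 1")


def make_helix(n_residues: int, noise_sd: float = 0.0, seed: int = 0,
               structure_id: str | None = None) -> ProteinStructure:
    """Synthetic helical protein with ``n_residues`` residues.

    CA atoms sit on the ideal helix; each residue additionally carries
    1-4 carbon "side-chain" atoms (count depends on residue type) placed
    radially outward from the helix axis.  Isotropic Gaussian noise of
    standard deviation ``noise_sd`` (A) perturbs every atom.
    """
    if n_residues < 2:
        raise ValueError("a helix needs at least 2 residues")
    rng = np.random.default_rng(seed)
    seq_idx = rng.integers(0, 20, size=n_residues)
    sequence = "".join(AMINO_ACIDS[i] for i in seq_idx)

    theta = np.deg2rad(HELIX_TURN) * np.arange(n_residues)
    ca = np.stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta),
         HELIX_RISE * np.arange(n_residues)], axis=1,
    )

    atoms: list[Atom] = []
    for i in range(n_residues):
        res3 = _one_to_three(sequence[i])
        noise = rng.normal(0.0, noise_sd, size=3) if noise_sd > 0 else np.zeros(3)
        atoms.append(Atom("C", i, res3, ca[i] + noise, True))
        n_side = 1 + (int(seq_idx[i]) % 4)  # residue-type-dependent, 1..4
        outward = np.array([np.cos(theta[i]), np.sin(theta[i]), 0.0])
        for j in range(n_side):
            pos = ca[i] + outward * (1.5 * (j + 1)) + np.array([0.0, 0.0, 0.3 * j])
            noise = rng.normal(0.0, noise_sd, size=3) if noise_sd > 0 else np.zeros(3)
            atoms.append(Atom("C", i, res3, pos + noise, False))

    sid = structure_id if structure_id is not None else f"helix_{n_residues}_{seed}"
    return ProteinStructure(id=sid, atoms=tuple(atoms), sequence=sequence)


def make_dataset(spec: FixtureSpec) -> list[ProteinStructure]:
    """``spec.n_structures`` helices with sizes uniform in ``residues_range``.

    Child seeds are derived from ``spec.seed`` through a SeedSequence spawn,
    so the dataset is reproducible and structures are mutually independent.
    """
    ss = np.random.SeedSequence(spec.seed)
    sizes_rng = np.random.default_rng(ss.spawn(1)[0])
    lo, hi = spec.residues_range
    sizes = sizes_rng.integers(lo, hi + 1, size=spec.n_structures)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(spec.n_structures + 1)[1:]]
    return [
        make_helix(int(n), spec.noise_sd, child_seeds[i], structure_id=f"fix{i:04d}")
        for i, n in enumerate(sizes)
    ]


def make_shared_factor_triples(n: int = 200, noise_sd: float = 0.5, seed: int = 0,
                               intrinsic_rank: int = 32):
    """Synthetic modality triples sharing a common 640-dim latent factor.

    Each protein draws a 640-dim factor f lying on a fixed random
    ``intrinsic_rank``-dimensional subspace (unit variance per coordinate);
    every modality observes its own fixed random orthogonal mixing of f plus
    independent Gaussian noise.  Returns (list of (seq, graph, cloud) vector
    triples, factor matrix (n, 640)).

    The low intrinsic rank keeps the shared structure identifiable from a few
    hundred samples (n must exceed the factor's effective dimension for any
    fusion model to generalize), mirroring at desk scale the regime of large
    pretraining corpora whose sample count dwarfs the embedding width.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 313]))
    d = 640
    u = rng.standard_normal((n, intrinsic_rank))
    basis = np.linalg.qr(rng.standard_normal((d, intrinsic_rank)))[0].T  # (r, d)
    factors = u @ basis * np.sqrt(d / intrinsic_rank)  # unit variance per dim
    mixes = [np.linalg.qr(rng.standard_normal((d, d)))[0] for _ in range(3)]
    triples = []
    for i in range(n):
        views = [factors[i] @ Q + rng.normal(0.0, noise_sd, size=d) for Q in mixes]
        triples.append(tuple(views))
    return triples, factors


def _one_to_three(letter: str) -> str:
    from .structures import _THREE_LETTER

    return _THREE_LETTER.get(letter, "UNK")


def _composition(sequence: str) -> np.ndarray:
    v = np.zeros(20)
    for ch in sequence:
        i = AMINO_ACIDS.find(ch)
        if i >= 0:
            v[i] += 1.0
    return v / max(len(sequence), 1)


def affinity_label(sequence: str, ligand_index: int, seed: int,
                   noise_sd: float = 0.0, rng: np.random.Generator | None = None) -> float:
    """Synthetic affinity: composition(protein) . w1 + w2[ligand] (+ noise).

    The weights w1 (20-dim) and w2 (one scalar per built-in ligand) are drawn
    once from ``seed``, so the noise-free label is exactly reproducible.
    """
    wrng = np.random.default_rng(np.random.SeedSequence([seed, 977]))
    w1 = wrng.normal(0.0, 1.0, size=20)
    w2 = wrng.normal(0.0, 1.0, size=len(BUILTIN_SMILES))
    y = float(_composition(sequence) @ w1 * 10.0 + w2[ligand_index % len(w2)])
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        y += float(rng.normal(0.0, noise_sd))
    return y


def make_affinity_task(structures, seed: int = 0, noise_sd: float = 0.0,
                       path=None) -> list[tuple[str, str, float]]:
    """Cross every structure with the built-in ligand list.

    Returns (protein_id, smiles, label) rows; optionally writes them as CSV
    with a header.  Labels follow :func:`affinity_label` under ``seed``.
    """
    if len(structures) < 2:
        raise ValueError("need at least 2 structures for a task table")
    noise_rng = np.random.default_rng(np.random.SeedSequence([seed, 1871]))
    rows = []
    for s in structures:
        for j, smi in enumerate(BUILTIN_SMILES):
            y = affinity_label(s.sequence, j, seed, noise_sd, rng=noise_rng)
            rows.append((s.id, smi, y))
    if path is not None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["protein_id", "smiles", "label"])
            w.writerows(rows)
    return rows
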