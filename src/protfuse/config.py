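"""Shared run configuration: training hyperparameters and dataset splits."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrainRun", "SplitSpec", "split_dataset"]


@dataclass(frozen=True)
class TrainRun:
    """Configuration for one training run of any of the three models.

    ``epochs`` defaults to 100, the pretraining duration used uniformly for
    all three models.  The seed determines every stochastic choice in the
    run: initialization, negative sampling, rotations, latent sampling.
    """

    epochs: int = 100
    learning_rate: float = 1e-3
    lr_decay: float = 1.0  # per-epoch multiplicative decay; 1.0 = constant
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must be in (0, 1]")


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test ratios (default 70:20:10) plus a shuffle seed."""

    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    seed: int = 0

    def __post_init__(self):
        if any(r <= 0 for r in self.ratios):
            raise ValueError("all split ratios must be positive")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")


def split_dataset(ids, spec: SplitSpec):
    """Seeded shuffle, then floor allocation with the remainder going to train.

    Returns (train_ids, val_ids, test_ids): disjoint, exhaustive, order of the
    shuffled permutation.
    """
    ids = list(ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 ids to split three ways")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    shuffled = [ids[i] for i in perm]
    n_val = int(np.floor(spec.ratios[1] * n))
    n_test = int(np.floor(spec.ratios[2] * n))
    n_train = n - n_val - n_test
    return (
        shuffled[:n_train],
        shuffled[n_train:n_train + n_val],
        shuffled[n_train + n_val:],
    )
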