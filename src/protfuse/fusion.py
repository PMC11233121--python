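"""Multimodal fusion: harmonize the three 640-dim branches and learn a joint code.

The graph branch yields a per-node latent matrix, reduced to one vector by
top-k pooling (the 640 highest-norm nodes averaged; all nodes if fewer).
Each branch is z-score normalized with statistics fit on the training split
only, then the three vectors are concatenated (sequence, graph, cloud) and
compressed 1920 -> 1280 -> 640 by the fusion autoencoder, which is trained
to reconstruct the concatenation under mean squared error.  The 640-dim
fusion latent is the protein representation used by every downstream head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import TrainRun
from .graph_vae import VGAEParams, gcn_encode
from .nn import Adam, Dense
from .point_autoencoder import PAEParams, pointnet_encode
from .point_cloud import build_point_cloud
from .residue_graph import build_residue_graph
from .sequence_embedding import SequenceEmbedder
from .structures import ProteinStructure

__all__ = [
    "ModalityTriple",
    "ZScoreStats",
    "AutoFusionParams",
    "FusedEncoder",
    "topk_node_pool",
    "zscore_fit",
    "zscore_apply",
    "autofusion_forward",
    "mse",
    "train_autofusion",
    "fuse",
    "CONCAT_DIM",
    "LATENT_DIM",
]

DIM = 640
CONCAT_DIM = 3 * DIM
HIDDEN_DIM = 1280
LATENT_DIM = 640
SD_FLOOR = 1e-8


@dataclass(frozen=True)
class ModalityTriple:
    """One protein's three unimodal vectors (each 640-dim)."""

    seq: np.ndarray
    graph: np.ndarray
    cloud: np.ndarray

    def __post_init__(self):
        for name in ("seq", "graph", "cloud"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (DIM,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} vector must be a finite {DIM}-vector")
            object.__setattr__(self, name, v)

    def concat(self) -> np.ndarray:
        """Fixed concatenation order: (sequence, graph, cloud)."""
        return np.concatenate([self.seq, self.graph, self.cloud])


@dataclass(frozen=True)
class ZScoreStats:
    """Per-dimension mean and floored standard deviation for one modality."""

    mean: np.ndarray
    sd: np.ndarray


def topk_node_pool(node_latents: np.ndarray, k: int = DIM) -> np.ndarray:
    """Average of the k highest-L2-norm rows (ties by lower index).

    With fewer than k nodes, all rows are averaged — no zero rows are
    invented, which would drag the mean toward zero.
    """
    node_latents = np.atleast_2d(np.asarray(node_latents, dtype=float))
    if node_latents.shape[0] < 1:
        raise ValueError("need at least one node latent")
    norms = np.linalg.norm(node_latents, axis=1)
    order = np.argsort(-norms, kind="stable")  # descending, ties -> lower index
    take = order[: min(k, len(order))]
    return node_latents[take].mean(axis=0)


def zscore_fit(vectors) -> ZScoreStats:
    """Per-dimension mean/sd over a training set of vectors (population sd)."""
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 vectors to fit z-score statistics")
    return ZScoreStats(mean=X.mean(axis=0), sd=np.maximum(X.std(axis=0), SD_FLOOR))


def zscore_apply(v: np.ndarray, stats: ZScoreStats) -> np.ndarray:
    """(v - mean) / sd; dimensions constant on the fit set map to exactly 0.

    A dimension with no training variance carries no calibrated scale, so
    any value there is uninformative and is zeroed rather than divided by
    the floor (which would explode on unseen inputs).
    """
    out = (np.asarray(v, dtype=float) - stats.mean) / stats.sd
    out[stats.sd <= SD_FLOOR] = 0.0
    return out


class AutoFusionParams:
    """Fusion autoencoder weights: 1920 -> 1280 -> 640 -> 1280 -> 1920, tanh hidden."""

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 71]))
        self.fuse1 = Dense(rng, CONCAT_DIM, HIDDEN_DIM)
        self.fuse2 = Dense(rng, HIDDEN_DIM, LATENT_DIM)
        self.rec1 = Dense(rng, LATENT_DIM, HIDDEN_DIM)
        self.rec2 = Dense(rng, HIDDEN_DIM, CONCAT_DIM)

    def layers(self):
        return [self.fuse1, self.fuse2, self.rec1, self.rec2]

    def param_grads(self):
        out = []
        for layer in self.layers():
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for layer in self.layers():
            layer.zero_grad()


def _forward_batch(params: AutoFusionParams, X: np.ndarray):
    h1 = np.tanh(params.fuse1.forward(X))
    latent = params.fuse2.forward(h1)
    h2 = np.tanh(params.rec1.forward(latent))
    recon = params.rec2.forward(h2)
    return latent, recon, (h1, h2)


def _backward_batch(params: AutoFusionParams, dRecon: np.ndarray, cache) -> None:
    h1, h2 = cache
    g = params.rec2.backward(dRecon)
    g = params.rec1.backward(g * (1.0 - h2 * h2))
    g = params.fuse2.backward(g)
    params.fuse1.backward(g * (1.0 - h1 * h1))


def autofusion_forward(t: ModalityTriple, params: AutoFusionParams):
    """(latent 640-vector, reconstruction 1920-vector) for one normalized triple."""
    latent, recon, _ = _forward_batch(params, t.concat()[None])
    return latent[0], recon[0]


def mse(x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error (1/n) sum_i (x_i - y_i)^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    return float(np.mean((x - y) ** 2))


def train_autofusion(triples, config: TrainRun, val_triples=None,
                     batch_size: int = 32):
    """Mini-batch MSE training of the fusion autoencoder.

    Each epoch shuffles the training triples (seeded) and takes one Adam
    step per mini-batch on the reconstruction MSE.  Returns (params,
    history) where history maps "train" (and "val" when a validation set is
    given) to mean reconstruction MSE; index 0 is the untrained model's MSE
    (the pre-training baseline), index e the value after epoch e.
    """
    triples = list(triples)
    if len(triples) < 2:
        raise ValueError("need at least 2 training triples")
    X = np.stack([t.concat() for t in triples])
    Xval = np.stack([t.concat() for t in val_triples]) if val_triples else None
    params = AutoFusionParams(seed=config.seed)
    opt = Adam(params.param_grads(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 79]))

    _, r0, _ = _forward_batch(params, X)
    history: dict[str, list[float]] = {"train": [float(np.mean((r0 - X) ** 2))]}
    if Xval is not None:
        _, rv0, _ = _forward_batch(params, Xval)
        history["val"] = [float(np.mean((rv0 - Xval) ** 2))]
    for _ in range(config.epochs):
        opt.lr *= config.lr_decay
        order = rng.permutation(len(X))
        epoch_losses = []
        for start in range(0, len(X), batch_size):
            B = X[order[start:start + batch_size]]
            _, recon, cache = _forward_batch(params, B)
            diff = recon - B
            epoch_losses.append(float(np.mean(diff**2)))
            params.zero_grad()
            _backward_batch(params, 2.0 * diff / diff.size, cache)
            opt.step()
        history["train"].append(float(np.mean(epoch_losses)))
        if Xval is not None:
            _, rv, _ = _forward_batch(params, Xval)
            history["val"].append(float(np.mean((rv - Xval) ** 2)))
    return params, history


def factor_probe_r2(latents: np.ndarray, factors: np.ndarray) -> float:
    """In-sample R^2 of a cross-validated ridge probe latent -> factor.

    With fewer samples than latent dimensions an out-of-sample linear map is
    unidentifiable, so the probe is fit and scored on the same latents; the
    cross-validated penalty keeps the score discriminative (uninformative
    latents force a large penalty and a near-zero R^2).
    """
    from sklearn.linear_model import RidgeCV

    probe = RidgeCV(alphas=np.logspace(-4, 4, 9)).fit(latents, factors)
    return float(probe.score(latents, factors))


@dataclass
class FusedEncoder:
    """Everything needed to map a structure to its 640-dim fused vector."""

    embedder: SequenceEmbedder
    vgae: VGAEParams
    pae: PAEParams
    autofusion: AutoFusionParams
    stats: dict  # modality name -> ZScoreStats, keys "seq", "graph", "cloud"
    k_neighbors: int = 5

    def modality_triple(self, s: ProteinStructure, normalized: bool = True) -> ModalityTriple:
        seq = self.embedder.embed(s.sequence)
        g = build_residue_graph(s, k=self.k_neighbors)
        graph = topk_node_pool(gcn_encode(g, self.vgae).mu)
        cloud = pointnet_encode(build_point_cloud(s, M=self.pae.M), self.pae)
        if normalized:
            seq = zscore_apply(seq, self.stats["seq"])
            graph = zscore_apply(graph, self.stats["graph"])
            cloud = zscore_apply(cloud, self.stats["cloud"])
        return ModalityTriple(seq=seq, graph=graph, cloud=cloud)

    def fuse(self, s: ProteinStructure) -> np.ndarray:
        latent, _ = autofusion_forward(self.modality_triple(s), self.autofusion)
        return latent


def fuse(protein: ProteinStructure, encoder: FusedEncoder) -> np.ndarray:
    """End-to-end: embed each modality, pool, normalize, compress to 640."""
    return encoder.fuse(protein)
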