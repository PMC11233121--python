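"""Variational graph autoencoder for residue graphs.

Two-layer GCN encoder (symmetric-normalized adjacency with self-loops)
producing per-node Gaussian latents, inner-product edge decoder, and a
negative-sampling reconstruction loss

    L_r = - sum_{(i,j) in E+} log p(i,j|Z) - sum_{(i,j) in E-} log(1 - p(i,j|Z))

with no KL term: the latent is used purely as a structural representation,
so the prior-matching pressure is deliberately dropped.  Pretraining is
evaluated as link prediction (held-out edges vs sampled non-edges, scored
with the posterior mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import average_precision_score, roc_auc_score

from .config import TrainRun
from .nn import Adam, glorot, sigmoid
from .residue_graph import N_CLASSES, ResidueGraph

__all__ = [
    "GaussianNodeLatent",
    "VGAEParams",
    "EdgeSplit",
    "init_vgae",
    "normalized_adjacency",
    "gcn_encode",
    "sample_latent",
    "inner_product_decode",
    "negative_sample",
    "reconstruction_loss",
    "train_vgae",
    "evaluate_link_prediction",
    "link_prediction_benchmark",
    "holdout_edges",
    "save_vgae",
    "load_vgae",
]

PROB_CLAMP = 1e-12


@dataclass(frozen=True)
class GaussianNodeLatent:
    """Per-node posterior: mean and log-variance, each (N, D)."""

    mu: np.ndarray
    logvar: np.ndarray

    def __post_init__(self):
        if self.mu.shape != self.logvar.shape:
            raise ValueError("mu and logvar shapes must match")


@dataclass
class VGAEParams:
    """Encoder weights: shared GCN layer then mu / logvar heads."""

    W1: np.ndarray      # (21, H)
    Wmu: np.ndarray     # (H, D)
    Wlogvar: np.ndarray  # (H, D)

    @property
    def hidden(self) -> int:
        return self.W1.shape[1]

    @property
    def latent(self) -> int:
        return self.Wmu.shape[1]


@dataclass(frozen=True)
class EdgeSplit:
    train_pos: frozenset
    held_out_pos: frozenset
    sampled_neg: frozenset


def init_vgae(hidden: int = 1024, latent: int = 640, seed: int = 0) -> VGAEParams:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    return VGAEParams(
        W1=glorot(rng, N_CLASSES, hidden),
        Wmu=glorot(rng, hidden, latent),
        Wlogvar=glorot(rng, hidden, latent),
    )


def normalized_adjacency(g: ResidueGraph) -> np.ndarray:
    """A_hat = D~^{-1/2} (A + I) D~^{-1/2} — the standard GCN propagation matrix."""
    A = g.adjacency() + np.eye(g.n_nodes)
    dinv = 1.0 / np.sqrt(A.sum(axis=1))
    return A * dinv[:, None] * dinv[None, :]


def gcn_encode(g: ResidueGraph, params: VGAEParams,
               a_hat: np.ndarray | None = None) -> GaussianNodeLatent:
    """H1 = ReLU(A_hat X W1); mu = A_hat H1 Wmu; logvar = A_hat H1 Wlogvar."""
    X = g.node_features
    if X.shape[1] != params.W1.shape[0]:
        raise ValueError("feature width does not match encoder input width")
    A = normalized_adjacency(g) if a_hat is None else a_hat
    H1 = np.maximum(A @ X @ params.W1, 0.0)
    Q = A @ H1
    return GaussianNodeLatent(mu=Q @ params.Wmu, logvar=Q @ params.Wlogvar)


def sample_latent(lat: GaussianNodeLatent, seed: int) -> np.ndarray:
    """Reparameterized draw Z = mu + exp(logvar/2) * eps, eps ~ N(0, I)."""
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(lat.mu.shape)
    return lat.mu + np.exp(0.5 * lat.logvar) * eps


def _pairs_array(pairs) -> np.ndarray:
    out = np.array(sorted(tuple(sorted(p)) for p in pairs), dtype=int)
    return out.reshape(-1, 2)


def inner_product_decode(Z: np.ndarray, pairs) -> np.ndarray:
    """Edge probability p(i,j) = logistic(z_i . z_j), one value per pair."""
    P = pairs if isinstance(pairs, np.ndarray) else _pairs_array(pairs)
    if P.size and P.max() >= Z.shape[0]:
        raise IndexError("pair index out of range")
    return sigmoid(np.einsum("ij,ij->i", Z[P[:, 0]], Z[P[:, 1]]))


def negative_sample(g: ResidueGraph, m: int, seed: int) -> frozenset:
    """m distinct unordered non-edges (no self-loops), uniform under seed."""
    n = g.n_nodes
    iu = np.triu_indices(n, k=1)
    all_pairs = np.stack(iu, axis=1)
    is_edge = np.array([frozenset((int(i), int(j))) in g.edges for i, j in all_pairs])
    non_edges = all_pairs[~is_edge]
    if m > len(non_edges):
        raise ValueError(f"requested {m} negatives but only {len(non_edges)} non-edges exist")
    rng = np.random.default_rng(seed)
    take = rng.choice(len(non_edges), size=m, replace=False)
    return frozenset(frozenset((int(i), int(j))) for i, j in non_edges[take])


def reconstruction_loss(p_pos: np.ndarray, p_neg: np.ndarray) -> float:
    """Summed negative log-likelihood over positive and negative pairs."""
    p_pos = np.clip(np.asarray(p_pos, dtype=float), PROB_CLAMP, 1 - PROB_CLAMP)
    p_neg = np.clip(np.asarray(p_neg, dtype=float), PROB_CLAMP, 1 - PROB_CLAMP)
    return float(-np.log(p_pos).sum() - np.log1p(-p_neg).sum())


def _train_step(g: ResidueGraph, params: VGAEParams, a_hat: np.ndarray,
                pos: np.ndarray, neg: np.ndarray, eps: np.ndarray):
    """One full-graph forward/backward pass; returns (loss, grads)."""
    X = g.node_features
    P = a_hat @ X                        # (N, 21)
    Z1 = P @ params.W1
    H1 = np.maximum(Z1, 0.0)
    Q = a_hat @ H1                       # (N, H)
    mu = Q @ params.Wmu
    logvar = Q @ params.Wlogvar
    sd = np.exp(0.5 * logvar)
    Z = mu + sd * eps

    pairs = np.vstack([pos, neg])
    s = np.einsum("ij,ij->i", Z[pairs[:, 0]], Z[pairs[:, 1]])
    p = sigmoid(s)
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    pc = np.clip(p, PROB_CLAMP, 1 - PROB_CLAMP)
    loss = float(-(y * np.log(pc) + (1 - y) * np.log1p(-pc)).sum())

    ds = p - y                           # d loss / d score
    dZ = np.zeros_like(Z)
    np.add.at(dZ, pairs[:, 0], ds[:, None] * Z[pairs[:, 1]])
    np.add.at(dZ, pairs[:, 1], ds[:, None] * Z[pairs[:, 0]])

    dmu = dZ
    dlogvar = dZ * eps * 0.5 * sd
    gWmu = Q.T @ dmu
    gWlogvar = Q.T @ dlogvar
    dQ = dmu @ params.Wmu.T + dlogvar @ params.Wlogvar.T
    dH1 = a_hat @ dQ                     # a_hat is symmetric
    dZ1 = dH1 * (Z1 > 0.0)
    gW1 = P.T @ dZ1
    return loss, (gW1, gWmu, gWlogvar)


def _remnant_a_hat(g: ResidueGraph, pos: np.ndarray, drop_mask: np.ndarray) -> np.ndarray:
    A = np.zeros((g.n_nodes, g.n_nodes))
    kept = pos[~drop_mask]
    A[kept[:, 0], kept[:, 1]] = 1.0
    A[kept[:, 1], kept[:, 0]] = 1.0
    A += np.eye(g.n_nodes)
    dinv = 1.0 / np.sqrt(A.sum(axis=1))
    return A * dinv[:, None] * dinv[None, :]


def train_vgae(dataset, config: TrainRun, hidden: int = 1024,
               latent: int = 640, neg_ratio: float = 1.0,
               edge_dropout: float = 0.1):
    """Link-prediction pretraining of the reconstruction loss over graphs.

    Each step processes one graph: a random ``edge_dropout`` fraction of its
    edges is hidden from the encoder input (the propagation matrix is built
    from the remnant), a fresh latent is sampled, and the loss scores all
    positive edges — seen and hidden — against |E+| * neg_ratio fresh
    negatives.  Hiding edges from the encoder makes the objective a true
    link-prediction task rather than adjacency echoing, matching how the
    model is evaluated.  Returns the trained parameters and the per-epoch
    mean (per-graph) loss history.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("dataset must contain at least one graph")
    params = init_vgae(hidden, latent, config.seed)
    grads = [np.zeros_like(params.W1), np.zeros_like(params.Wmu),
             np.zeros_like(params.Wlogvar)]
    opt = Adam([(params.W1, grads[0]), (params.Wmu, grads[1]),
                (params.Wlogvar, grads[2])], lr=config.learning_rate)
    full_a_hats = [normalized_adjacency(g) for g in dataset]
    pos_arrays = [g.edge_array() for g in dataset]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))

    history = []
    for _ in range(config.epochs):
        losses = []
        for g, full_a_hat, pos in zip(dataset, full_a_hats, pos_arrays):
            if edge_dropout > 0:
                drop = rng.random(len(pos)) < edge_dropout
                a_hat = _remnant_a_hat(g, pos, drop) if drop.any() else full_a_hat
            else:
                a_hat = full_a_hat
            n_non_edges = g.n_nodes * (g.n_nodes - 1) // 2 - len(g.edges)
            m = min(max(1, int(round(neg_ratio * len(pos)))), n_non_edges)
            neg = _pairs_array(negative_sample(g, m, int(rng.integers(2**31))))
            eps = rng.standard_normal((g.n_nodes, latent))
            loss, (g1, g2, g3) = _train_step(g, params, a_hat, pos, neg, eps)
            grads[0][...] = g1
            grads[1][...] = g2
            grads[2][...] = g3
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return params, history


def holdout_edges(g: ResidueGraph, holdout_frac: float, seed: int,
                  max_tries: int = 50) -> EdgeSplit:
    """Hold out a fraction of edges such that the remnant stays connected."""
    edges = _pairs_array(g.edges)
    n_hold = max(1, int(round(holdout_frac * len(edges))))
    if n_hold >= len(edges):
        raise ValueError("holdout would empty the graph")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        take = rng.choice(len(edges), size=n_hold, replace=False)
        mask = np.zeros(len(edges), dtype=bool)
        mask[take] = True
        remnant = edges[~mask]
        A = np.zeros((g.n_nodes, g.n_nodes))
        A[remnant[:, 0], remnant[:, 1]] = 1.0
        A[remnant[:, 1], remnant[:, 0]] = 1.0
        if connected_components(A, directed=False)[0] == 1:
            held = frozenset(frozenset((int(i), int(j))) for i, j in edges[mask])
            train = frozenset(frozenset((int(i), int(j))) for i, j in remnant)
            n_non_edges = g.n_nodes * (g.n_nodes - 1) // 2 - len(edges)
            neg = negative_sample(g, min(n_hold, n_non_edges),
                                  int(rng.integers(2**31)))
            return EdgeSplit(train_pos=train, held_out_pos=held, sampled_neg=neg)
    raise ValueError("could not find a connected training remnant")


def evaluate_link_prediction(params: VGAEParams, graphs, holdout_frac: float = 0.1,
                             seed: int = 0) -> tuple[float, float]:
    """Pooled link-prediction AUC and average precision over held-out edges.

    For each graph a fraction of edges is held out, the remnant graph is
    encoded, and held-out positives are scored against an equal number of
    sampled non-edges using the posterior mean (no latent sampling).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    scores, labels = [], []
    for g in graphs:
        split = holdout_edges(g, holdout_frac, int(rng.integers(2**31)))
        remnant = ResidueGraph(node_features=g.node_features,
                               edges=split.train_pos, n_nodes=g.n_nodes)
        mu = gcn_encode(remnant, params).mu
        p_pos = inner_product_decode(mu, split.held_out_pos)
        p_neg = inner_product_decode(mu, split.sampled_neg)
        scores.extend([*p_pos, *p_neg])
        labels.extend([1] * len(p_pos) + [0] * len(p_neg))
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    return float(roc_auc_score(labels, scores)), float(average_precision_score(labels, scores))


def link_prediction_benchmark(graphs, config: TrainRun, holdout_frac: float = 0.1,
                              hidden: int = 1024, latent: int = 640):
    """Canonical link-prediction evaluation: hold out, train on remnants, predict.

    A fraction of each graph's edges is removed up front; the model trains on
    the remnant graphs only (the held-out edges appear in neither the
    propagation matrix nor the loss) and is then scored on the held-out
    positives against equal-count sampled non-edges, pooled over graphs.

    Returns (params, auc, ap).
    """
    graphs = list(graphs)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 37]))
    splits = [holdout_edges(g, holdout_frac, int(rng.integers(2**31))) for g in graphs]
    remnants = [ResidueGraph(node_features=g.node_features, edges=sp.train_pos,
                             n_nodes=g.n_nodes) for g, sp in zip(graphs, splits)]
    params, _ = train_vgae(remnants, config, hidden=hidden, latent=latent)
    scores, labels = [], []
    for rem, sp in zip(remnants, splits):
        mu = gcn_encode(rem, params).mu
        p_pos = inner_product_decode(mu, sp.held_out_pos)
        p_neg = inner_product_decode(mu, sp.sampled_neg)
        scores.extend([*p_pos, *p_neg])
        labels.extend([1] * len(p_pos) + [0] * len(p_neg))
    auc = float(roc_auc_score(labels, scores))
    ap = float(average_precision_score(labels, scores))
    return params, auc, ap


def save_vgae(params: VGAEParams, path) -> None:
    np.savez(path, W1=params.W1, Wmu=params.Wmu, Wlogvar=params.Wlogvar)


def load_vgae(path) -> VGAEParams:
    with np.load(path) as f:
        return VGAEParams(W1=f["W1"], Wmu=f["Wmu"], Wlogvar=f["Wlogvar"])
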