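"""PointNet-style autoencoder over standardized protein point clouds.

Encoder: a shared per-point MLP (3 -> 64 -> 128 -> code) followed by a
symmetric element-wise max over points, which makes the code exactly
invariant to point order.  Decoder: an MLP (code -> 512 -> 256 -> 256 -> 3M,
ReLU + batch normalization after each hidden layer) reshaped to an M x 3
cloud.  Training minimizes the chamfer distance

    CD(X, Y) = sum_x min_y ||x - y||^2 + sum_y min_x ||y - x||^2

with a fresh uniform random rotation applied to the real points of each
cloud at every step, so the encoder learns orientation robustness rather
than having it imposed architecturally.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .config import TrainRun
from .nn import Adam, BatchNorm, Dense
from .point_cloud import PointCloud

__all__ = [
    "PAEParams",
    "CODE_DIM",
    "pointnet_encode",
    "decode",
    "chamfer_distance",
    "random_rotation",
    "train_pae",
    "evaluate_cd",
    "save_pae",
    "load_pae",
]

CODE_DIM = 640


class PAEParams:
    """Encoder/decoder weights for a fixed cloud size M."""

    def __init__(self, M: int, seed: int = 0, code_dim: int = CODE_DIM):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 47]))
        self.M = M
        self.code_dim = code_dim
        self.enc = [Dense(rng, 3, 64), Dense(rng, 64, 128), Dense(rng, 128, code_dim)]
        self.dec_dense = [Dense(rng, code_dim, 512), Dense(rng, 512, 256),
                          Dense(rng, 256, 256), Dense(rng, 256, 3 * M)]
        self.dec_bn = [BatchNorm(512), BatchNorm(256), BatchNorm(256)]
        self._cache = None

    def set_training(self, flag: bool) -> None:
        for bn in self.dec_bn:
            bn.training = flag

    def layers(self):
        return [*self.enc, *self.dec_dense, *self.dec_bn]

    def param_grads(self):
        out = []
        for layer in self.layers():
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for layer in self.layers():
            layer.zero_grad()


def _encode_batch(params: PAEParams, P: np.ndarray):
    """P: (B, M, 3) -> codes (B, C); caches activations for backprop."""
    B, M, _ = P.shape
    z1 = params.enc[0].forward(P.reshape(-1, 3))
    a1 = np.maximum(z1, 0.0)
    z2 = params.enc[1].forward(a1)
    a2 = np.maximum(z2, 0.0)
    z3 = params.enc[2].forward(a2)
    F = z3.reshape(B, M, -1)
    code = F.max(axis=1)
    cache = (z1 > 0, z2 > 0, F.argmax(axis=1), B, M)
    return code, cache


def _encode_backward(params: PAEParams, dcode: np.ndarray, cache) -> None:
    m1, m2, argmax, B, M = cache
    C = dcode.shape[1]
    dF = np.zeros((B, M, C))
    np.put_along_axis(dF, argmax[:, None, :], dcode[:, None, :], axis=1)
    da2 = params.enc[2].backward(dF.reshape(-1, C))
    da1 = params.enc[1].backward(da2 * m2)
    params.enc[0].backward(da1 * m1)


def _decode_batch(params: PAEParams, code: np.ndarray):
    """code: (B, C) -> reconstruction (B, M, 3); caches ReLU masks."""
    masks = []
    h = code
    for dense, bn in zip(params.dec_dense[:-1], params.dec_bn):
        z = dense.forward(h)
        a = np.maximum(z, 0.0)
        masks.append(z > 0)
        h = bn.forward(a)
    out = params.dec_dense[-1].forward(h)
    return out.reshape(code.shape[0], params.M, 3), masks


def _decode_backward(params: PAEParams, dout: np.ndarray, masks) -> np.ndarray:
    g = params.dec_dense[-1].backward(dout.reshape(dout.shape[0], -1))
    for dense, bn, mask in zip(reversed(params.dec_dense[:-1]),
                               reversed(params.dec_bn), reversed(masks)):
        g = bn.backward(g)
        g = dense.backward(g * mask)
    return g


def pointnet_encode(cloud: PointCloud, params: PAEParams) -> np.ndarray:
    """Deterministic 640-dim code of one cloud (eval path)."""
    if cloud.M != params.M:
        raise ValueError("cloud size M does not match parameters")
    code, _ = _encode_batch(params, cloud.points[None])
    return code[0]


def decode(code: np.ndarray, params: PAEParams, M: int | None = None) -> np.ndarray:
    """Reconstruct an (M, 3) cloud from a code, with frozen normalization."""
    if M is not None and M != params.M:
        raise ValueError("M does not match decoder output width")
    was_training = params.dec_bn[0].training
    params.set_training(False)
    out, _ = _decode_batch(params, np.asarray(code, dtype=float)[None])
    params.set_training(was_training)
    return out[0]


def chamfer_distance(X: np.ndarray, Y: np.ndarray, reduction: str = "sum") -> float:
    """Symmetric nearest-neighbour squared-distance loss between point sets.

    ``reduction='sum'`` is the summed form above; ``'mean'`` divides each
    directed term by its set size (scale-comparable across cloud sizes).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 0 or Y.shape[0] == 0:
        raise ValueError("point sets must be nonempty")
    D2 = cdist(X, Y, metric="sqeuclidean")
    t1, t2 = D2.min(axis=1), D2.min(axis=0)
    if reduction == "sum":
        return float(t1.sum() + t2.sum())
    if reduction == "mean":
        return float(t1.mean() + t2.mean())
    raise ValueError("reduction must be 'sum' or 'mean'")


def _chamfer_grad(X: np.ndarray, Y: np.ndarray) -> tuple[float, np.ndarray]:
    """Summed CD(X, Y) and its gradient with respect to Y."""
    D2 = cdist(X, Y, metric="sqeuclidean")
    j_near = D2.argmin(axis=1)   # nearest y for each x
    i_near = D2.argmin(axis=0)   # nearest x for each y
    loss = float(D2[np.arange(len(X)), j_near].sum() +
                 D2[i_near, np.arange(len(Y))].sum())
    gY = 2.0 * (Y - X[i_near])
    np.add.at(gY, j_near, 2.0 * (Y[j_near] - X))
    return loss, gY


def random_rotation(seed: int) -> np.ndarray:
    """Haar-uniform rotation matrix from a normalized Gaussian quaternion."""
    rng = np.random.default_rng(seed)
    q = rng.standard_normal(4)
    w, x, y, z = q / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def train_pae(dataset, config: TrainRun, augment: bool = True,
              batch_size: int = 8, mask_padding: bool = False):
    """Chamfer-distance training over a list of equal-size clouds.

    Every step applies a fresh random rotation to the real points of each
    cloud in the mini-batch (padding rows stay zero), encodes, decodes and
    takes one Adam step on the batch-mean summed chamfer distance.  Padded
    zero rows participate in the loss unless ``mask_padding``.

    Returns (params, per-epoch mean training CD).
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("dataset must contain at least one cloud")
    M = dataset[0].M
    if any(c.M != M for c in dataset):
        raise ValueError("all clouds must share the same M")
    params = PAEParams(M, seed=config.seed)
    opt = Adam(params.param_grads(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 53]))
    params.set_training(True)

    history = []
    for _ in range(config.epochs):
        order = rng.permutation(len(dataset))
        losses = []
        for start in range(0, len(dataset), batch_size):
            batch = [dataset[i] for i in order[start:start + batch_size]]
            P = np.stack([c.points for c in batch])
            if augment:
                for b, c in enumerate(batch):
                    R = random_rotation(int(rng.integers(2**31)))
                    P[b, :c.n_real] = P[b, :c.n_real] @ R.T
            code, enc_cache = _encode_batch(params, P)
            recon, masks = _decode_batch(params, code)

            B = len(batch)
            total, dRecon = 0.0, np.zeros_like(recon)
            for b, c in enumerate(batch):
                target = P[b, :c.n_real] if mask_padding else P[b]
                loss_b, gY = _chamfer_grad(target, recon[b])
                total += loss_b
                dRecon[b] = gY / B
            losses.append(total / B)

            params.zero_grad()
            dcode = _decode_backward(params, dRecon, masks)
            _encode_backward(params, dcode, enc_cache)
            opt.step()
        history.append(float(np.mean(losses)))
    params.set_training(False)
    return params, history


def evaluate_cd(params: PAEParams, clouds, mask_padding: bool = False) -> float:
    """Mean reconstruction chamfer distance on unrotated clouds (eval mode)."""
    params.set_training(False)
    cds = []
    for c in clouds:
        recon = decode(pointnet_encode(c, params), params)
        target = c.real_points() if mask_padding else c.points
        cds.append(chamfer_distance(target, recon))
    return float(np.mean(cds))


def save_pae(params: PAEParams, path) -> None:
    arrays = {"M": np.array(params.M), "code_dim": np.array(params.code_dim)}
    for i, d in enumerate(params.enc):
        arrays[f"enc{i}_W"], arrays[f"enc{i}_b"] = d.W, d.b
    for i, d in enumerate(params.dec_dense):
        arrays[f"dec{i}_W"], arrays[f"dec{i}_b"] = d.W, d.b
    for i, bn in enumerate(params.dec_bn):
        arrays[f"bn{i}_gamma"], arrays[f"bn{i}_beta"] = bn.gamma, bn.beta
        arrays[f"bn{i}_mean"], arrays[f"bn{i}_var"] = bn.run_mean, bn.run_var
    np.savez(path, **arrays)


def load_pae(path) -> PAEParams:
    with np.load(path) as f:
        params = PAEParams(int(f["M"]), seed=0, code_dim=int(f["code_dim"]))
        for i, d in enumerate(params.enc):
            d.W[...], d.b[...] = f[f"enc{i}_W"], f[f"enc{i}_b"]
        for i, d in enumerate(params.dec_dense):
            d.W[...], d.b[...] = f[f"dec{i}_W"], f[f"dec{i}_b"]
        for i, bn in enumerate(params.dec_bn):
            bn.gamma[...], bn.beta[...] = f[f"bn{i}_gamma"], f[f"bn{i}_beta"]
            bn.run_mean[...], bn.run_var[...] = f[f"bn{i}_mean"], f[f"bn{i}_var"]
    params.set_training(False)
    return params
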