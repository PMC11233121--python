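"""Downstream task heads and the affinity metric suite.

Protein-ligand affinity: a Gaussian-process regressor over the fused protein
vector concatenated with a Morgan fingerprint of the ligand.  Fold / enzyme /
mutation-stability classification: a gradient-boosted tree classifier over
the fused vector (wild-type and mutant vectors concatenated for stability
pairs).  Metrics cover the standard drug-target-affinity suite, including
the concordance index and rm^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.metrics import roc_auc_score

__all__ = [
    "AffinityExample",
    "PairExample",
    "ligand_fingerprint",
    "fit_affinity_head",
    "predict_affinity",
    "fit_classifier_head",
    "predict_classifier",
    "concordance_index",
    "rm2_index",
    "metrics",
]


@dataclass(frozen=True)
class AffinityExample:
    protein_vec: np.ndarray   # 640-dim fused representation
    ligand_bits: np.ndarray   # binary fingerprint
    label: float


@dataclass(frozen=True)
class PairExample:
    wt_vec: np.ndarray
    mut_vec: np.ndarray
    label: int  # 1 if the mutation improves binding


def ligand_fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048) -> np.ndarray:
    """Morgan (circular-substructure) fingerprint as a dense 0/1 vector."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits)
    for bit in fp.GetOnBits():
        arr[bit] = 1.0
    return arr


def _affinity_matrix(examples) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([np.concatenate([e.protein_vec, e.ligand_bits]) for e in examples])
    y = np.array([e.label for e in examples], dtype=float)
    return X, y


class _AffinityModel:
    """Feature scaler + GP regressor bundle."""

    def __init__(self, scaler, gp):
        self.scaler = scaler
        self.gp = gp

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.gp.predict(self.scaler.transform(X))


def fit_affinity_head(train, seed: int = 0, noise_level: float = 1e-3):
    """GP regression on (protein ‖ fingerprint) features, RBF + white kernel.

    Feature columns are standardized before the kernel (embedding and
    fingerprint blocks live on very different numeric scales) and the RBF
    length-scale starts at the median pairwise training distance; targets
    are standardized internally (normalize_y).  Constant targets get a
    warning and degrade gracefully to the mean predictor.
    """
    from sklearn.preprocessing import StandardScaler

    train = list(train)
    if len(train) < 3:
        raise ValueError("need at least 3 training examples")
    X, y = _affinity_matrix(train)
    if np.ptp(y) == 0.0:
        warnings.warn("constant training targets; GP reduces to the mean predictor")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    from scipy.spatial.distance import pdist

    dists = pdist(Xs)
    scale = float(np.median(dists[dists > 0])) if np.any(dists > 0) else 1.0
    kernel = ConstantKernel(1.0) * RBF(length_scale=scale) + WhiteKernel(
        noise_level=noise_level, noise_level_bounds=(1e-8, 1e2)
    )
    gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        gp.fit(Xs, y)
    return _AffinityModel(scaler, gp)


def predict_affinity(model, examples) -> np.ndarray:
    X, _ = _affinity_matrix(list(examples))
    return model.predict(X)


def fit_classifier_head(X: np.ndarray, y: np.ndarray, seed: int = 0,
                        n_estimators: int = 300, max_depth: int = 6,
                        learning_rate: float = 0.1):
    """Seeded gradient-boosted tree classifier over embedding features."""
    import xgboost as xgb

    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    model = xgb.XGBClassifier(
        n_estimators=n_estimators, max_depth=max_depth, learning_rate=learning_rate,
        random_state=seed, n_jobs=1, eval_metric="logloss", tree_method="hist",
    )
    model.fit(np.asarray(X, dtype=float), y)
    return model


def predict_classifier(model, X: np.ndarray) -> np.ndarray:
    """Class probabilities, shape (n, n_classes)."""
    return model.predict_proba(np.asarray(X, dtype=float))


def concordance_index(y_true, y_pred) -> float:
    """Fraction of concordant pairs among pairs with distinct true labels.

    Prediction ties score half a point; pairs with tied true labels are
    excluded.  1 = perfect ranking, 0.5 = random, 0 = fully reversed.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    dt = y_true[:, None] - y_true[None, :]
    dp = y_pred[:, None] - y_pred[None, :]
    iu = np.triu_indices(len(y_true), k=1)
    dt, dp = dt[iu], dp[iu]
    valid = dt != 0
    if not valid.any():
        raise ValueError("concordance index undefined for constant y_true")
    agree = np.sign(dt[valid]) == np.sign(dp[valid])
    tied = dp[valid] == 0
    return float((agree[~tied].sum() + 0.5 * tied.sum()) / valid.sum())


def rm2_index(y_true, y_pred) -> float:
    """rm^2 = r^2 (1 - sqrt(|r^2 - r0^2|)); r0^2 is the through-origin fit.

    r^2 is the squared Pearson correlation of predictions with observations;
    r0^2 is the coefficient of determination of the best through-origin
    scaling of predictions, k = sum(y yhat)/sum(yhat^2).
    """
    y = np.asarray(y_true, dtype=float)
    f = np.asarray(y_pred, dtype=float)
    if y.shape != f.shape:
        raise ValueError("length mismatch")
    r = sps.pearsonr(y, f)[0]
    r2 = r * r
    k = float(f @ y / (f @ f))
    ss_res0 = float(((y - k * f) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r0_2 = 1.0 - ss_res0 / ss_tot
    return float(r2 * (1.0 - np.sqrt(abs(r2 - r0_2))))


def metrics(y_true, y_pred=None, y_score=None) -> dict[str, float]:
    """Named metric values for whichever inputs apply.

    Regression metrics (mse, rmse, mae, pearson, spearman, ci, rm2) need
    ``y_pred``; classification metrics (accuracy from argmax-able scores,
    auroc for binary labels) need ``y_score``.
    """
    y_true = np.asarray(y_true, dtype=float)
    out: dict[str, float] = {}
    if y_pred is not None:
        y_pred = np.asarray(y_pred, dtype=float)
        if y_pred.shape != y_true.shape:
            raise ValueError("length mismatch")
        err = y_pred - y_true
        out["mse"] = float(np.mean(err**2))
        out["rmse"] = float(np.sqrt(out["mse"]))
        out["mae"] = float(np.mean(np.abs(err)))
        out["pearson"] = float(sps.pearsonr(y_true, y_pred)[0])
        out["spearman"] = float(sps.spearmanr(y_true, y_pred)[0])
        out["ci"] = concordance_index(y_true, y_pred)
        out["rm2"] = rm2_index(y_true, y_pred)
    if y_score is not None:
        y_score = np.asarray(y_score, dtype=float)
        if y_score.ndim == 2:
            out["accuracy"] = float(np.mean(y_score.argmax(axis=1) == y_true))
            if y_score.shape[1] == 2:
                out["auroc"] = float(roc_auc_score(y_true, y_score[:, 1]))
        else:
            out["accuracy"] = float(np.mean((y_score >= 0.5) == y_true))
            out["auroc"] = float(roc_auc_score(y_true, y_score))
    return out
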