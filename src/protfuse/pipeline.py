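"""End-to-end orchestration: featurize, pretrain all three models, fuse, embed.

A single :class:`PipelineConfig` (YAML-serializable) drives every stage; the
global seed determines all stochastic choices — splits, initializations,
negative samples, rotations, latent draws — so a rerun with the same config
reproduces every loss history and embedding byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import SplitSpec, TrainRun, split_dataset
from .fixtures import FixtureSpec, make_dataset
from .fusion import (AutoFusionParams, FusedEncoder, ModalityTriple,
                     topk_node_pool, train_autofusion, zscore_apply, zscore_fit)
from .graph_vae import evaluate_link_prediction, gcn_encode, train_vgae
from .point_autoencoder import evaluate_cd, pointnet_encode, train_pae
from .point_cloud import build_point_cloud
from .residue_graph import build_residue_graph
from .sequence_embedding import toy_embedder
from .structures import ProteinStructure, parse_pdb

__all__ = ["PipelineConfig", "run_pipeline", "load_structures", "embed_structures"]

log = logging.getLogger("protfuse")


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs for one pipeline run, with desk-scale defaults."""

    seed: int = 0
    # fixture generation (ignored when a PDB directory is supplied)
    n_structures: int = 60
    residues_range: tuple[int, int] = (30, 60)
    noise_sd: float = 0.3
    # featurization
    k_neighbors: int = 5
    n_points: int = 256          # cloud size M; desk-scale default
    # training
    vgae_epochs: int = 100
    pae_epochs: int = 100
    fusion_epochs: int = 100
    learning_rate: float = 1e-3
    split: tuple[float, float, float] = (0.7, 0.2, 0.1)
    vgae_hidden: int = 1024
    latent_dim: int = 640

    def to_yaml(self) -> str:
        d = asdict(self)
        d["residues_range"] = list(d["residues_range"])
        d["split"] = list(d["split"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        if "residues_range" in d:
            d["residues_range"] = tuple(d["residues_range"])
        if "split" in d:
            d["split"] = tuple(d["split"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def load_structures(pdb_dir) -> list[ProteinStructure]:
    """Parse every *.pdb file in a directory, sorted by filename."""
    paths = sorted(Path(pdb_dir).glob("*.pdb"))
    if not paths:
        raise FileNotFoundError(f"no .pdb files under {pdb_dir}")
    return [parse_pdb(p) for p in paths]


def _check_run_dir(out_dir: Path, cfg: PipelineConfig) -> None:
    marker = out_dir / "config_hash.txt"
    if marker.exists():
        previous = marker.read_text().strip()
        if previous != cfg.config_hash():
            raise RuntimeError(
                f"run directory {out_dir} holds a run with config hash {previous}, "
                f"but the current config hashes to {cfg.config_hash()}; refusing to mix runs"
            )
    out_dir.mkdir(parents=True, exist_ok=True)
    marker.write_text(cfg.config_hash() + "\n")
    (out_dir / "config.yaml").write_text(cfg.to_yaml())


def run_pipeline(cfg: PipelineConfig, out_dir=None,
                 structures: list[ProteinStructure] | None = None) -> dict:
    """Run featurize -> pretrain (VGAE, PAE, Auto-Fusion) -> fuse -> embed.

    Returns a dict with the trained :class:`FusedEncoder`, the embedding
    table (DataFrame, one 640-dim row per protein) and a metrics summary.
    If ``out_dir`` is given, embeddings (CSV), metrics (JSON), the config
    and its hash are written there.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        _check_run_dir(out_path, cfg)
    log.info("pipeline start: config hash %s seed %d", cfg.config_hash(), cfg.seed)

    if structures is None:
        structures = make_dataset(FixtureSpec(
            n_structures=cfg.n_structures, residues_range=cfg.residues_range,
            noise_sd=cfg.noise_sd, seed=cfg.seed))
    ids = [s.id for s in structures]
    by_id = {s.id: s for s in structures}
    train_ids, val_ids, test_ids = split_dataset(ids, SplitSpec(cfg.split, cfg.seed))
    log.info("split %d/%d/%d structures", len(train_ids), len(val_ids), len(test_ids))

    # --- graph branch
    graphs = {i: build_residue_graph(by_id[i], k=cfg.k_neighbors) for i in ids}
    vgae_params, vgae_hist = train_vgae(
        [graphs[i] for i in train_ids],
        TrainRun(epochs=cfg.vgae_epochs, learning_rate=cfg.learning_rate, seed=cfg.seed),
        hidden=cfg.vgae_hidden, latent=cfg.latent_dim)
    auc, ap = evaluate_link_prediction(vgae_params, [graphs[i] for i in test_ids],
                                       holdout_frac=0.1, seed=cfg.seed)
    log.info("VGAE: final loss %.3f, test link AUC %.3f AP %.3f", vgae_hist[-1], auc, ap)

    # --- point-cloud branch
    clouds = {i: build_point_cloud(by_id[i], M=cfg.n_points) for i in ids}
    pae_params, pae_hist = train_pae(
        [clouds[i] for i in train_ids],
        TrainRun(epochs=cfg.pae_epochs, learning_rate=cfg.learning_rate, seed=cfg.seed))
    test_cd = evaluate_cd(pae_params, [clouds[i] for i in test_ids])
    log.info("PAE: final train CD %.4f, test CD %.4f", pae_hist[-1], test_cd)

    # --- sequence branch + fusion
    raw = {
        i: {
            "seq": toy_embedder.embed(by_id[i].sequence),
            "graph": topk_node_pool(gcn_encode(graphs[i], vgae_params).mu),
            "cloud": pointnet_encode(clouds[i], pae_params),
        }
        for i in ids
    }
    stats = {m: zscore_fit([raw[i][m] for i in train_ids]) for m in ("seq", "graph", "cloud")}

    def triple(i: str) -> ModalityTriple:
        return ModalityTriple(**{m: zscore_apply(raw[i][m], stats[m]) for m in raw[i]})

    fusion_params, fusion_hist = train_autofusion(
        [triple(i) for i in train_ids],
        TrainRun(epochs=cfg.fusion_epochs, learning_rate=cfg.learning_rate, seed=cfg.seed),
        val_triples=[triple(i) for i in val_ids])
    log.info("Auto-Fusion: train MSE %.4f, val MSE %.4f",
             fusion_hist["train"][-1], fusion_hist["val"][-1])

    encoder = FusedEncoder(embedder=toy_embedder, vgae=vgae_params, pae=pae_params,
                           autofusion=fusion_params, stats=stats,
                           k_neighbors=cfg.k_neighbors)
    embeddings = embed_structures(encoder, structures)

    summary = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_structures": len(structures),
        "vgae": {"final_train_loss": vgae_hist[-1], "test_auc": auc, "test_ap": ap},
        "pae": {"final_train_cd": pae_hist[-1], "test_cd": test_cd},
        "fusion": {"final_train_mse": fusion_hist["train"][-1],
                   "final_val_mse": fusion_hist["val"][-1]},
    }
    if out_path is not None:
        embeddings.to_csv(out_path / "embeddings.csv", float_format="%.10g")
        (out_path / "metrics.json").write_text(json.dumps(summary, indent=2) + "\n")
        log.info("artifacts written to %s", out_path)

    return {
        "encoder": encoder,
        "embeddings": embeddings,
        "summary": summary,
        "splits": {"train": train_ids, "val": val_ids, "test": test_ids},
        "histories": {"vgae": vgae_hist, "pae": pae_hist, "fusion": fusion_hist},
        "structures": by_id,
    }


def embed_structures(encoder: FusedEncoder, structures) -> pd.DataFrame:
    """One fused 640-dim row per protein, indexed by protein id."""
    rows = {s.id: encoder.fuse(s) for s in structures}
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"z{i:03d}" for i in range(640)])
    df.index.name = "protein_id"
    return df
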