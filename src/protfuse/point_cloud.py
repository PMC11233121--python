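"""Atomic point clouds: center, scale to the unit sphere, pad/trim to M points.

Standardization removes translation (centering) and global size (unit-sphere
scaling); orientation is deliberately left in place and handled downstream by
rotation augmentation during autoencoder training.  Clouds are padded with
zero vectors (which after centering sit at the centroid) or trimmed to a
fixed count M so batches are uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import ProteinStructure

__all__ = [
    "PointCloud",
    "DegenerateCloudError",
    "center",
    "scale_unit_sphere",
    "fix_point_count",
    "build_point_cloud",
    "write_xyz",
    "DEFAULT_M",
]

DEFAULT_M = 2048


class DegenerateCloudError(ValueError):
    """All points coincident — no scale can be defined."""


@dataclass(frozen=True)
class PointCloud:
    """Fixed-size standardized cloud; rows >= n_real are zero padding."""

    points: np.ndarray  # (M, 3), dimensionless after scaling
    n_real: int
    M: int

    def __post_init__(self):
        if self.points.shape != (self.M, 3):
            raise ValueError("points must be (M, 3)")
        if not 0 < self.n_real <= self.M:
            raise ValueError("n_real must be in (0, M]")

    def real_points(self) -> np.ndarray:
        return self.points[: self.n_real]


def center(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Translate the centroid c = mean(p_i) to the origin; returns (p - c, c)."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 1 or points.shape[1] != 3:
        raise ValueError("need an (N, 3) array with N >= 1")
    c = points.mean(axis=0)
    return points - c, c


def scale_unit_sphere(points: np.ndarray) -> np.ndarray:
    """Divide by r_max = max ||p_i|| so the cloud fits in the unit sphere."""
    points = np.asarray(points, dtype=float)
    r_max = float(np.linalg.norm(points, axis=1).max())
    if r_max <= 0.0:
        raise DegenerateCloudError("all points coincide; cannot scale")
    return points / r_max


def fix_point_count(points: np.ndarray, M: int) -> np.ndarray:
    """Pad with zero rows up to M, or keep the first M rows (input order)."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 1 or M < 1:
        raise ValueError("need N >= 1 and M >= 1")
    if n < M:
        return np.vstack([points, np.zeros((M - n, 3))])
    return points[:M].copy()


def build_point_cloud(s: ProteinStructure, M: int = DEFAULT_M,
                      subsample_seed: int | None = None) -> PointCloud:
    """Structure -> standardized cloud: center, scale, then pad/trim to M.

    Trimming keeps the first M atoms in record order; pass ``subsample_seed``
    to instead draw a uniform subsample of M atoms (seeded, order-preserving).
    """
    coords = s.atom_coords()
    if coords.shape[0] > M and subsample_seed is not None:
        rng = np.random.default_rng(subsample_seed)
        keep = np.sort(rng.choice(coords.shape[0], size=M, replace=False))
        coords = coords[keep]
    centered, _ = center(coords)
    scaled = scale_unit_sphere(centered)
    return PointCloud(points=fix_point_count(scaled, M),
                      n_real=min(coords.shape[0], M), M=M)


def write_xyz(cloud: PointCloud, path, comment: str = "") -> None:
    """Dump the real (non-padded) points in XYZ format for inspection."""
    pts = cloud.real_points()
    with open(path, "w") as fh:
        fh.write(f"{len(pts)}\n{comment}\n")
        for x, y, z in pts:
            fh.write(f"C {x:.6f} {y:.6f} {z:.6f}\n")
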