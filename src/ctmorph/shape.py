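"""Strain-level shape analysis: alignment, probability maps, consensus
shapes, surface distance maps and the Dice overlap statistic."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from ._mesh import surface_mesh
from .preprocess import BinaryMask

__all__ = [
    "ShapeProbabilityMap",
    "SurfaceDistanceSummary",
    "align_shape_labels",
    "shape_probability_map",
    "consensus_shape",
    "surface_distance_map",
    "dice_coefficient",
]


@dataclass
class ShapeProbabilityMap:
    """Voxel-wise presence frequency of a structure across aligned specimens."""

    data: np.ndarray  # values in [0, 1], multiples of 1/n
    n_specimens: int
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SurfaceDistanceSummary:
    a_to_b: np.ndarray  # µm per vertex of A's surface
    b_to_a: np.ndarray
    mean_a_to_b: float
    mean_b_to_a: float
    max_a_to_b: float
    max_b_to_a: float
    symmetric_mean: float

    def as_dict(self) -> dict:
        return {
            "mean_a_to_b": self.mean_a_to_b,
            "mean_b_to_a": self.mean_b_to_a,
            "max_a_to_b": self.max_a_to_b,
            "max_b_to_a": self.max_b_to_a,
            "symmetric_mean": self.symmetric_mean,
        }


def _principal_axis(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of the second-moment tensor of centred coords."""
    cov = coords.T @ coords / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    return evals[::-1], evecs[:, ::-1]  # descending


def align_shape_labels(
    masks: list[BinaryMask], eigenvalue_gap: float = 0.01
) -> list[BinaryMask]:
    """Align each mask to a canonical pose: centroid at the grid centre and
    the principal axis of the second-moment tensor along z, with the heavier
    mass half placed anterior (low z).  Nearly isotropic shapes (relative
    gap between the two largest eigenvalues below ``eigenvalue_gap``) are
    only translated, with a warning."""
    if not masks:
        raise ValueError("no masks to align")
    out: list[BinaryMask] = []
    for mask in masks:
        data = np.asarray(mask.data, dtype=bool)
        if not data.any():
            raise ValueError("empty mask cannot be aligned")
        spacing = np.asarray(mask.spacing)
        idx = np.argwhere(data).astype(np.float64)
        phys = idx * spacing
        centroid = phys.mean(axis=0)
        evals, evecs = _principal_axis(phys - centroid)
        gap = (evals[0] - evals[1]) / max(evals[0], 1e-12)
        if gap < eigenvalue_gap:
            warnings.warn(
                "degenerate principal axis; translation-only alignment",
                stacklevel=2,
            )
            rot = np.eye(3)
        else:
            axis = evecs[:, 0]
            rot = _rotation_to_z(axis)
            # anterior-heavier convention: put the heavier half at low z
            z_proj = (phys - centroid) @ rot.T[:, 0]
            if np.mean(z_proj < 0) < 0.5:
                rot = _rotation_to_z(-axis)
        grid_center = (np.asarray(data.shape) - 1) / 2.0 * spacing
        # pull-back resample: output voxel -> rotate back -> source voxel
        out_idx = np.indices(data.shape).reshape(3, -1).T * spacing - grid_center
        src = (out_idx @ rot) + centroid  # rot.T applied, inverse of rot
        src_idx = (src / spacing).T
        resampled = ndimage.map_coordinates(
            data.astype(np.uint8), src_idx, order=0, mode="constant", cval=0
        ).reshape(data.shape)
        out.append(BinaryMask(resampled.astype(bool), mask.spacing, mask.origin))
    return out


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix sending ``axis`` to the +z unit vector (z, y, x frame)."""
    a = axis / np.linalg.norm(axis)
    z = np.array([1.0, 0.0, 0.0])
    v = np.cross(a, z)
    c = float(a @ z)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    vx = np.array(
        [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]]
    )
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def shape_probability_map(aligned: list[BinaryMask]) -> ShapeProbabilityMap:
    """Voxel-wise mean of aligned binary masks."""
    if not aligned:
        raise ValueError("no masks given")
    shape = aligned[0].shape
    for m in aligned[1:]:
        if m.shape != shape or m.spacing != aligned[0].spacing:
            raise ValueError("masks must share shape and spacing")
    stack = np.stack([np.asarray(m.data, dtype=np.float64) for m in aligned])
    return ShapeProbabilityMap(
        data=stack.mean(axis=0),
        n_specimens=len(aligned),
        spacing=aligned[0].spacing,
        origin=aligned[0].origin,
    )


def consensus_shape(
    prob_map: ShapeProbabilityMap, threshold: float = 0.60
) -> BinaryMask:
    """Consensus mask {p >= threshold}; the boundary is inclusive so a voxel
    present in exactly 60% of specimens belongs to the 60% consensus."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    return BinaryMask(
        prob_map.data >= threshold - 1e-12, prob_map.spacing, prob_map.origin
    )


def surface_distance_map(
    shape_a: BinaryMask, shape_b: BinaryMask
) -> SurfaceDistanceSummary:
    """Unsigned distances between the isosurfaces of two pre-aligned shapes.

    For every vertex of A's surface the Euclidean distance to the nearest
    vertex of B's surface is computed (and vice versa); summaries are
    reported in both directions plus the symmetric mean.
    """
    if not np.asarray(shape_a.data).any() or not np.asarray(shape_b.data).any():
        raise ValueError("empty shape has no surface")
    va, _ = surface_mesh(shape_a.data, shape_a.spacing)
    vb, _ = surface_mesh(shape_b.data, shape_b.spacing)
    va = va + np.asarray(shape_a.origin)
    vb = vb + np.asarray(shape_b.origin)
    d_ab = cKDTree(vb).query(va, workers=-1)[0]
    d_ba = cKDTree(va).query(vb, workers=-1)[0]
    return SurfaceDistanceSummary(
        a_to_b=d_ab,
        b_to_a=d_ba,
        mean_a_to_b=float(d_ab.mean()),
        mean_b_to_a=float(d_ba.mean()),
        max_a_to_b=float(d_ab.max()),
        max_b_to_a=float(d_ba.max()),
        symmetric_mean=float((d_ab.mean() + d_ba.mean()) / 2.0),
    )


def dice_coefficient(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); two empty masks count as identical
    (Dice 1.0, documented convention)."""
    da = np.asarray(a.data if isinstance(a, BinaryMask) else a, dtype=bool)
    db = np.asarray(b.data if isinstance(b, BinaryMask) else b, dtype=bool)
    if da.shape != db.shape:
        raise ValueError(f"grid mismatch: {da.shape} vs {db.shape}")
    na, nb = int(da.sum()), int(db.sum())
    if na + nb == 0:
        return 1.0
    inter = int((da & db).sum())
    return 2.0 * inter / (na + nb)
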