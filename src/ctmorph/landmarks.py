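"""Connected-component shape analysis and the three-point landmark alignment.

Lens detection follows the premise that eye lenses image as low-absorption,
near-spherical regions enclosed by the body: connected components of the
below-Otsu ("water-like") class inside the body mask are screened by
sphericity, and the pair of candidates with the most similar volumes is
declared the lenses.  Together with a tail point (centroid of the posterior
30% of the body mask) the two lens centroids define a three-point similarity
transform used to initialise atlas registration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._mesh import surface_area
from .preprocess import BinaryMask, otsu_threshold
from .register import AffineTransform
from .volio import Volume3D

__all__ = [
    "RegionProps",
    "LandmarkSet",
    "label_regions",
    "detect_lenses",
    "find_landmarks",
    "similarity_from_landmarks",
    "sphericity",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def sphericity(volume: float, area: float) -> float:
    """Wadell's sphericity pi^(1/3) (6V)^(2/3) / A (1 for a perfect ball)."""
    if volume <= 0 or area <= 0:
        raise ValueError("volume and area must be positive")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)


@dataclass
class RegionProps:
    """Shape descriptors of one connected component (physical µm units)."""

    id: int
    volume: float  # µm³, voxel count x voxel volume
    voxel_count: int
    surface_area: float  # µm², isosurface estimate
    centroid: tuple[float, float, float]  # µm, (z, y, x)
    sphericity: float
    bbox_lo: tuple[int, int, int]  # half-open voxel box [lo, hi)
    bbox_hi: tuple[int, int, int]


@dataclass
class LandmarkSet:
    """Lens centroids (left/right by y) and tail point, physical µm.

    Convention: anterior at low z, so the tail has the largest z.
    """

    lens_left: tuple[float, float, float]
    lens_right: tuple[float, float, float]
    tail: tuple[float, float, float]

    def __post_init__(self) -> None:
        if np.allclose(self.lens_left, self.lens_right):
            raise ValueError("lens landmarks must be distinct")
        if self.tail[0] <= max(self.lens_left[0], self.lens_right[0]):
            raise ValueError(
                "tail must be posterior (larger z) to both lenses"
            )

    def as_array(self) -> np.ndarray:
        return np.asarray([self.lens_left, self.lens_right, self.tail], dtype=float)

    def translated(self, offset) -> "LandmarkSet":
        off = np.asarray(offset, dtype=float)
        return LandmarkSet(
            tuple(np.asarray(self.lens_left) + off),
            tuple(np.asarray(self.lens_right) + off),
            tuple(np.asarray(self.tail) + off),
        )


def label_regions(mask: BinaryMask, spacing=None) -> list[RegionProps]:
    """26-connected components of a binary mask with volume, surface area,
    centroid, sphericity and bounding box per component."""
    spacing = tuple(spacing) if spacing is not None else mask.spacing
    data = np.asarray(mask.data, dtype=bool)
    lab, n = ndimage.label(data, structure=_STRUCT_26)
    if n == 0:
        return []
    voxel_vol = float(np.prod(spacing))
    origin = getattr(mask, "origin", (0.0, 0.0, 0.0))
    objects = ndimage.find_objects(lab)
    out: list[RegionProps] = []
    for rid, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = lab[sl] == rid
        count = int(sub.sum())
        vol = count * voxel_vol
        area = surface_area(sub, spacing)
        idx = np.argwhere(sub).astype(np.float64)
        lo = np.array([s.start for s in sl])
        centroid = tuple(
            (idx.mean(axis=0) + lo) * np.asarray(spacing) + np.asarray(origin)
        )
        out.append(
            RegionProps(
                id=rid,
                volume=vol,
                voxel_count=count,
                surface_area=area,
                centroid=centroid,
                sphericity=sphericity(vol, area),
                bbox_lo=tuple(int(s.start) for s in sl),
                bbox_hi=tuple(int(s.stop) for s in sl),
            )
        )
    return out


def detect_lenses(
    vol: Volume3D,
    body_mask: BinaryMask,
    min_sphericity: float = 0.85,
    min_volume_vox: int = 100,
) -> tuple[RegionProps, RegionProps]:
    """Find the two eye lenses.

    Candidates are connected components of {intensity <= Otsu threshold}
    inside the body mask with sphericity >= ``min_sphericity`` and at least
    ``min_volume_vox`` voxels.  Among all candidate pairs (i, j) the volume
    self-similarity score S_ij = |V_i - V_j| / (V_i + V_j) is minimised;
    ties are broken by the largest sphericity sum.  The pair is returned
    ordered (left, right) by y centroid.
    """
    t = otsu_threshold(vol)
    water = (np.asarray(vol.data) <= t) & np.asarray(body_mask.data, dtype=bool)
    regions = label_regions(
        BinaryMask(water, vol.spacing, vol.origin)
    )
    candidates = [
        r
        for r in regions
        if r.sphericity >= min_sphericity and r.voxel_count >= min_volume_vox
    ]
    if len(candidates) < 2:
        raise ValueError(
            f"lenses not found: {len(candidates)} candidate region(s) after "
            f"sphericity/volume screening"
        )
    best_pairs: list[tuple[RegionProps, RegionProps]] = []
    best_score = np.inf
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            a, b = candidates[i], candidates[j]
            s = abs(a.volume - b.volume) / (a.volume + b.volume)
            if s < best_score - 1e-12:
                best_score, best_pairs = s, [(a, b)]
            elif abs(s - best_score) <= 1e-12:
                best_pairs.append((a, b))
    if len(best_pairs) > 1:
        psi = [a.sphericity + b.sphericity for a, b in best_pairs]
        order = np.argsort(psi)[::-1]
        if len(best_pairs) > 1 and abs(psi[order[0]] - psi[order[1]]) <= 1e-12:
            listing = ", ".join(
                f"(vol {a.volume:.0f}/{b.volume:.0f}, psi {a.sphericity:.3f}/{b.sphericity:.3f})"
                for a, b in best_pairs
            )
            raise ValueError(f"ambiguous lens pair: {listing}")
        pair = best_pairs[int(order[0])]
    else:
        pair = best_pairs[0]
    a, b = pair
    return (a, b) if a.centroid[1] <= b.centroid[1] else (b, a)


def find_landmarks(
    vol: Volume3D,
    body_mask: BinaryMask,
    posterior_fraction: float = 0.30,
    **lens_kwargs,
) -> LandmarkSet:
    """Three landmarks: both lens centroids and the tail point (centroid of
    body-mask voxels in the posterior ``posterior_fraction`` of the mask's
    z extent)."""
    left, right = detect_lenses(vol, body_mask, **lens_kwargs)
    zs = np.flatnonzero(body_mask.data.any(axis=(1, 2)))
    if zs.size == 0:
        raise ValueError("empty body mask")
    z_min, z_max = int(zs[0]), int(zs[-1])
    z_cut = z_max - posterior_fraction * (z_max - z_min)
    slab = body_mask.data.copy()
    slab[: int(np.ceil(z_cut))] = False
    idx = np.argwhere(slab)
    if idx.size == 0:
        raise ValueError("empty posterior slab")
    tail = tuple(
        idx.mean(axis=0) * np.asarray(body_mask.spacing)
        + np.asarray(body_mask.origin)
    )
    return LandmarkSet(lens_left=left.centroid, lens_right=right.centroid, tail=tail)


def similarity_from_landmarks(
    moving: LandmarkSet, fixed: LandmarkSet, collinear_tol: float = 1e-6
) -> AffineTransform:
    """Least-squares similarity transform (rotation + isotropic scale +
    translation, Umeyama closed form) mapping the moving landmarks onto the
    fixed ones.  The residual RMS is attached as ``residual_rms``."""
    src = moving.as_array()
    dst = fixed.as_array()
    for pts, name in ((src, "moving"), (dst, "fixed")):
        area = 0.5 * np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0]))
        scale_ref = max(np.ptp(pts), 1.0)
        if area < collinear_tol * scale_ref**2:
            raise ValueError(f"degenerate landmark configuration ({name} points collinear)")

    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    xs = src - mu_s
    xd = dst - mu_d
    cov = xd.T @ xs / src.shape[0]
    u, s, vt = np.linalg.svd(cov)
    d = np.ones(3)
    if np.linalg.det(u) * np.linalg.det(vt) < 0:
        d[-1] = -1.0
    rot = u @ np.diag(d) @ vt
    var_s = (xs**2).sum() / src.shape[0]
    scale = float((s * d).sum() / var_s)
    linear = scale * rot
    translation = mu_d - linear @ mu_s
    transform = AffineTransform(linear, translation)
    residuals = transform.apply(src) - dst
    transform.residual_rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return transform
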