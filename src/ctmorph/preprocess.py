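"""Whole-body masking, thresholding, stitching, denoising and dataset QC."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import ball
from skimage.restoration import denoise_nl_means

from .volio import Volume3D

__all__ = [
    "BinaryMask",
    "QCReport",
    "otsu_threshold",
    "compute_body_mask",
    "stitch_subvolumes",
    "denoise_nlm",
    "qc_screen",
    "bhattacharyya_distance",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class BinaryMask:
    """Boolean grid aligned with its source volume."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def as_volume(self) -> Volume3D:
        return Volume3D(self.data.astype(np.float32), self.spacing, self.origin)

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class QCReport:
    complete: bool
    histogram_ok: bool
    hist_divergence: float | None = None
    tissue_contrast_z: float | None = None
    tissue_ok: bool = True

    @property
    def passed(self) -> bool:
        return self.complete and self.histogram_ok and self.tissue_ok

    def as_dict(self) -> dict:
        return {
            "complete": self.complete,
            "histogram_ok": self.histogram_ok,
            "hist_divergence": self.hist_divergence,
            "tissue_contrast_z": self.tissue_contrast_z,
            "tissue_ok": self.tissue_ok,
            "passed": self.passed,
        }


def otsu_threshold(vol: Volume3D | np.ndarray, nbins: int = 256) -> float:
    """Threshold maximising the between-class variance of the two-class split
    {<= t, > t}; ties broken by the smallest t.

    When the data take no more than ``nbins`` distinct values the candidate
    thresholds are the exact values themselves, so the result matches an
    exhaustive search; otherwise an ``nbins``-bin histogram is used and the
    candidates are the lower bin edges.
    """
    data = vol.data if isinstance(vol, Volume3D) else np.asarray(vol)
    flat = data.ravel().astype(np.float64)
    uniq, counts = np.unique(flat, return_counts=True)
    if uniq.size < 2:
        raise ValueError("degenerate histogram: volume is constant")
    if uniq.size > nbins:
        counts, edges = np.histogram(flat, bins=nbins)
        values = edges[:-1]  # lower bin edges as candidate thresholds
    else:
        values = uniq
    # candidates t = values[k]: class0 = bins 0..k, class1 = rest
    w = counts.astype(np.float64)
    total = w.sum()
    cw = np.cumsum(w)
    cm = np.cumsum(w * values)
    mean_total = cm[-1] / total
    omega0 = cw / total
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cm / cw
        mu1 = (cm[-1] - cm) / (total - cw)
    sigma_b = omega0 * omega1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=-np.inf)  # last split is degenerate
    # smallest t wins among (numerically) tied maximisers; plateaus are real
    # on gapped histograms and float rounding must not pick inside them
    peak = sigma_b.max()
    best = int(np.flatnonzero(sigma_b >= peak * (1.0 - 1e-12))[0])
    return float(values[best])


def compute_body_mask(vol: Volume3D, closing_radius_vox: int = 3) -> BinaryMask:
    """Whole-body binary mask: Otsu threshold, morphological closing with a
    ball structuring element, largest connected component, then filling of
    enclosed cavities (a whole-body mask must contain low-intensity interior
    structures such as the lenses)."""
    t = otsu_threshold(vol)
    fg = np.asarray(vol.data) > t
    if not fg.any():
        raise ValueError("empty foreground after thresholding")
    if closing_radius_vox > 0:
        fg = ndimage.binary_closing(
            fg, structure=ball(closing_radius_vox), border_value=0
        )
    lab, n = ndimage.label(fg, structure=_STRUCT_26)
    if n == 0:
        raise ValueError("empty foreground after closing")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    mask = lab == keep
    mask = ndimage.binary_fill_holes(mask)
    return BinaryMask(mask, vol.spacing, vol.origin)


def stitch_subvolumes(
    parts: Sequence[Volume3D],
    max_shift_vox: int | None = None,
    min_overlap: int = 8,
    min_correlation: float = 0.5,
) -> Volume3D:
    """Combine consecutive sub-volumes along z into one volume.

    For each consecutive pair the integer overlap is found by maximising the
    normalised cross-correlation between the trailing slab of the first part
    and the leading slab of the second; the overlap zone is blended with a
    linear ramp.  ``max_shift_vox`` optionally caps the overlap searched.
    """
    if len(parts) == 0:
        raise ValueError("no parts to stitch")
    for p in parts[1:]:
        if p.shape[1:] != parts[0].shape[1:]:
            raise ValueError("parts must share in-plane shape")
        if p.spacing != parts[0].spacing:
            raise ValueError("parts must share spacing")
    result = np.asarray(parts[0].data, dtype=np.float64)
    for part in parts[1:]:
        b = np.asarray(part.data, dtype=np.float64)
        max_o = min(result.shape[0], b.shape[0])
        if max_shift_vox is not None:
            max_o = min(max_o, int(max_shift_vox))
        if max_o < min_overlap:
            raise ValueError(
                f"parts must overlap by at least {min_overlap} slices"
            )
        best_o, best_ncc = None, -np.inf
        for o in range(min_overlap, max_o + 1):
            a_slab = result[-o:].ravel()
            b_slab = b[:o].ravel()
            sa, sb = a_slab.std(), b_slab.std()
            if sa == 0 or sb == 0:
                continue
            ncc = float(
                np.mean((a_slab - a_slab.mean()) * (b_slab - b_slab.mean()))
                / (sa * sb)
            )
            if ncc >= best_ncc:  # ties resolved in favour of the larger overlap
                best_o, best_ncc = o, ncc
        if best_o is None or best_ncc < min_correlation:
            raise ValueError(
                f"no reliable overlap found (best correlation {best_ncc:.3f})"
            )
        o = best_o
        ramp = np.linspace(0.0, 1.0, o + 2)[1:-1][:, None, None]
        blend = result[-o:] * (1.0 - ramp) + b[:o] * ramp
        result = np.concatenate([result[:-o], blend, b[o:]], axis=0)
    return Volume3D(result, parts[0].spacing, parts[0].origin)


def denoise_nlm(
    vol: Volume3D,
    patch_radius: int = 1,
    search_radius: int = 3,
    h: float = 10.0,
) -> Volume3D:
    """Non-local means denoising (delegates to scikit-image).

    ``h`` is the smoothing strength in intensity units; as h -> 0 the filter
    approaches the identity.
    """
    if patch_radius <= 0 or search_radius <= 0:
        raise ValueError("patch_radius and search_radius must be positive")
    data = np.asarray(vol.data, dtype=np.float64)
    if h <= 0:
        return Volume3D(data.copy(), vol.spacing, vol.origin)
    out = denoise_nl_means(
        data,
        patch_size=2 * patch_radius + 1,
        patch_distance=search_radius,
        h=h,
        fast_mode=True,
        preserve_range=True,
    )
    return Volume3D(out, vol.spacing, vol.origin)


def bhattacharyya_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Bhattacharyya distance -ln(sum sqrt(p_i q_i)) of two histograms
    (normalised internally)."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("histograms must share binning")
    p = p / p.sum()
    q = q / q.sum()
    bc = float(np.sum(np.sqrt(p * q)))
    return float(-np.log(max(bc, 1e-300)))


def qc_screen(
    vol: Volume3D,
    mask: BinaryMask,
    reference_hist: tuple[np.ndarray, np.ndarray] | None = None,
    tissue_samples: tuple[np.ndarray, np.ndarray] | None = None,
    hist_threshold: float = 0.2,
    z_threshold: float = 1.96,
) -> QCReport:
    """Screen a dataset before segmentation; always returns a report.

    ``complete`` fails when the body mask touches the first or last z slice
    (specimen larger than the imaged region).  ``histogram_ok`` fails when
    the Bhattacharyya distance between the volume's intensity histogram and
    a reference histogram ``(counts, bin_edges)`` exceeds the threshold.
    ``tissue_samples`` optionally supplies two intensity samples of the same
    tissue from different specimens; their two-sample z statistic is
    reported and flagged when |z| exceeds ``z_threshold``.
    """
    if mask.shape != vol.shape:
        raise ValueError("mask and volume shapes differ")
    complete = not (mask.data[0].any() or mask.data[-1].any())

    histogram_ok = True
    divergence = None
    if reference_hist is not None:
        ref_counts, edges = reference_hist
        counts, _ = np.histogram(np.asarray(vol.data).ravel(), bins=edges)
        divergence = bhattacharyya_distance(counts, ref_counts)
        histogram_ok = divergence <= hist_threshold

    z_stat = None
    tissue_ok = True
    if tissue_samples is not None:
        a = np.asarray(tissue_samples[0], dtype=np.float64).ravel()
        b = np.asarray(tissue_samples[1], dtype=np.float64).ravel()
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        z_stat = float((a.mean() - b.mean()) / max(se, 1e-300))
        tissue_ok = abs(z_stat) <= z_threshold

    return QCReport(
        complete=complete,
        histogram_ok=histogram_ok,
        hist_divergence=divergence,
        tissue_contrast_z=z_stat,
        tissue_ok=tissue_ok,
    )
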