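"""Volumetric containers and I/O.

All grids are indexed ``(z, y, x)`` with z the antero-posterior axis
(anterior at low z).  Physical units are micrometres throughout; a voxel
with index ``(k, j, i)`` sits at physical position ``origin + index * spacing``.
Coordinates are 0-based and bounding boxes half-open ``[lo, hi)``.

Supported on-disk formats: NRRD and MetaImage (``.mha``/``.mhd``) via
SimpleITK, and multi-page TIFF stacks via tifffile (TIFF carries no
spacing metadata here; a default of 1 µm is used with a warning).

An atlas is stored as a directory bundle::

    atlas_dir/
        reference.nrrd   # grayscale reference volume
        labels.nrrd      # integer label map, 0 = background
        organs.json      # [{"id": 1, "name": "lens_left",
                         #   "group": "eyes", "is_lens": true}, ...]
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Volume3D",
    "LabelMap",
    "Organ",
    "Atlas",
    "load_volume",
    "save_volume",
    "load_atlas",
    "save_atlas",
    "export_morphometrics",
    "import_morphometrics",
]


def _as_triple(values, name: str) -> tuple[float, float, float]:
    vals = tuple(float(v) for v in values)
    if len(vals) != 3:
        raise ValueError(f"{name} must have 3 components, got {len(vals)}")
    return vals


@dataclass
class Volume3D:
    """A 3-D scalar grid with per-axis voxel spacing (µm) and origin (µm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"degenerate grid shape {self.data.shape}")
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in µm³."""
        return float(np.prod(self.spacing))

    def physical_coords(self) -> np.ndarray:
        """Physical (z, y, x) coordinates of every voxel centre, shape (N, 3)."""
        idx = np.indices(self.shape, dtype=np.float64).reshape(3, -1).T
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def crop(self, lo: Sequence[int], hi: Sequence[int]) -> "Volume3D":
        """Half-open crop ``[lo, hi)`` with the origin shifted accordingly."""
        lo = tuple(int(v) for v in lo)
        hi = tuple(int(v) for v in hi)
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        origin = tuple(
            o + a * s for o, a, s in zip(self.origin, lo, self.spacing)
        )
        return replace(self, data=self.data[sl].copy(), origin=origin)

    def copy(self) -> "Volume3D":
        return replace(self, data=self.data.copy())


@dataclass(frozen=True)
class Organ:
    id: int
    name: str
    group: str | None = None
    is_lens: bool = False


@dataclass
class LabelMap(Volume3D):
    """An integer grid aligned with a :class:`Volume3D`; 0 is background."""

    organ_table: dict[int, Organ] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"label data must be integer, got {self.data.dtype}")
        if self.data.min() < 0:
            raise ValueError("label ids must be non-negative")
        self.organ_table = {int(k): v for k, v in self.organ_table.items()}

    def validate_table(self) -> None:
        present = self.present_ids()
        missing = sorted(set(present) - set(self.organ_table))
        if missing:
            raise ValueError(f"label ids without organ-table entry: {missing}")

    def present_ids(self) -> list[int]:
        ids = np.unique(self.data)
        return [int(i) for i in ids if i != 0]

    def organ_mask(self, organ_id: int) -> np.ndarray:
        return self.data == organ_id

    def lens_ids(self) -> list[int]:
        return [o.id for o in self.organ_table.values() if o.is_lens]


@dataclass
class Atlas:
    """Reference volume plus label map in a canonical coordinate frame.

    The frame convention is fixed: axis 0 (z) is antero-posterior with the
    anterior end at low z.
    """

    reference: Volume3D
    labels: LabelMap
    organ_groups: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reference.shape != self.labels.shape:
            raise ValueError(
                f"reference shape {self.reference.shape} != "
                f"labels shape {self.labels.shape}"
            )
        if self.reference.spacing != self.labels.spacing:
            raise ValueError("reference and labels must share spacing")
        self.labels.validate_table()
        if not self.labels.organ_table:
            raise ValueError("atlas must define at least one organ")
        if not self.organ_groups:
            groups: dict[str, list[int]] = {}
            for organ in self.labels.organ_table.values():
                if organ.group:
                    groups.setdefault(organ.group, []).append(organ.id)
            self.organ_groups = groups

    @property
    def organ_table(self) -> dict[int, Organ]:
        return self.labels.organ_table

    def lens_ids(self) -> list[int]:
        return self.labels.lens_ids()


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------

_SITK_EXTENSIONS = {".nrrd", ".nhdr", ".mha", ".mhd"}
_TIFF_EXTENSIONS = {".tif", ".tiff"}


def _normalise_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower().lstrip(".")
        if fmt in {"nrrd", "mha", "mhd", "metaimage"}:
            return "sitk"
        if fmt in {"tif", "tiff"}:
            return "tiff"
        raise ValueError(
            f"unsupported format {format!r}; supported: NRRD, MetaImage (.mha/.mhd), TIFF"
        )
    ext = path.suffix.lower()
    if ext in _SITK_EXTENSIONS:
        return "sitk"
    if ext in _TIFF_EXTENSIONS:
        return "tiff"
    raise ValueError(
        f"cannot infer format from {path.name!r}; supported extensions: "
        f"{sorted(_SITK_EXTENSIONS | _TIFF_EXTENSIONS)}"
    )


def load_volume(path, format: str | None = None) -> Volume3D:
    """Read a volume from NRRD, MetaImage or a multi-page TIFF stack.

    Spacing and origin are taken from the header for NRRD/MetaImage.  TIFF
    stacks carry no spacing metadata in this scheme; spacing defaults to
    (1, 1, 1) µm with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    kind = _normalise_format(path, format)
    if kind == "sitk":
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as exc:  # pragma: no cover - exercised via bad files
            raise ValueError(f"unreadable volume file {path}: {exc}") from exc
        data = sitk.GetArrayFromImage(img)  # (z, y, x)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected 3-D data, got ndim={data.ndim}")
        spacing = tuple(reversed(img.GetSpacing()))  # sitk is (x, y, z)
        origin = tuple(reversed(img.GetOrigin()))
        return Volume3D(data=data, spacing=spacing, origin=origin)
    import tifffile

    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D TIFF stack, got ndim={data.ndim}")
    warnings.warn(
        f"{path.name}: TIFF stack carries no spacing metadata; "
        "defaulting to (1, 1, 1) µm",
        stacklevel=2,
    )
    return Volume3D(data=data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0))


def save_volume(vol: Volume3D, path, format: str | None = None) -> None:
    """Write a volume; the format is inferred from the extension by default."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    kind = _normalise_format(path, format)
    data = vol.data
    if kind == "sitk":
        import SimpleITK as sitk

        if data.dtype == np.bool_:
            data = data.astype(np.uint8)
        img = sitk.GetImageFromArray(np.ascontiguousarray(data))
        img.SetSpacing(tuple(reversed(vol.spacing)))
        img.SetOrigin(tuple(reversed(vol.origin)))
        sitk.WriteImage(img, str(path))
        return
    import tifffile

    tifffile.imwrite(str(path), np.ascontiguousarray(data))


# ---------------------------------------------------------------------------
# Atlas bundle I/O
# ---------------------------------------------------------------------------


def _organ_to_json(o: Organ) -> dict:
    return {"id": o.id, "name": o.name, "group": o.group, "is_lens": o.is_lens}


def save_atlas(atlas: Atlas, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_volume(atlas.reference, directory / "reference.nrrd")
    save_volume(atlas.labels, directory / "labels.nrrd")
    payload = {
        "organs": [_organ_to_json(o) for o in atlas.organ_table.values()],
        "frame": "z antero-posterior, anterior at low z; index order (z, y, x)",
    }
    (directory / "organs.json").write_text(json.dumps(payload, indent=2))


def load_atlas(directory) -> Atlas:
    directory = Path(directory)
    ref = load_volume(directory / "reference.nrrd")
    lab_vol = load_volume(directory / "labels.nrrd")
    if not np.issubdtype(lab_vol.data.dtype, np.integer):
        raise ValueError("atlas label volume must be integer-typed")
    payload = json.loads((directory / "organs.json").read_text())
    table = {
        int(o["id"]): Organ(
            id=int(o["id"]),
            name=str(o["name"]),
            group=o.get("group"),
            is_lens=bool(o.get("is_lens", False)),
        )
        for o in payload["organs"]
    }
    labels = LabelMap(
        data=lab_vol.data,
        spacing=lab_vol.spacing,
        origin=lab_vol.origin,
        organ_table=table,
    )
    return Atlas(reference=ref, labels=labels)


# ---------------------------------------------------------------------------
# Morphometrics table export
# ---------------------------------------------------------------------------

MORPHOMETRICS_COLUMNS = [
    "specimen_id",
    "organ_id",
    "organ_name",
    "volume_um3",
    "surface_area_um2",
    "centroid_z_um",
    "centroid_y_um",
    "centroid_x_um",
    "width_um",
    "height_um",
    "length_um",
    "volume_norm",
    "surface_norm",
    "width_norm",
    "height_norm",
    "length_norm",
]


def export_morphometrics(records: Iterable, path) -> None:
    """Write morphometric records as CSV, one row per (specimen, organ).

    Floats are serialised with 12 significant digits so a re-import
    round-trips within float parsing error.
    """
    rows = [rec.as_row() if hasattr(rec, "as_row") else dict(rec) for rec in records]
    df = pd.DataFrame(rows, columns=MORPHOMETRICS_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def import_morphometrics(path) -> pd.DataFrame:
    return pd.read_csv(path)
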