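"""Volume and raster I/O, 3D-to-2D slicing, and dataset manifests.

The staging pipeline operates on 2D grayscale slices.  Clinical inputs
arrive as 3D volumes (NIfTI files or DICOM series); this module loads
them, slices them along the axial (first) axis and tracks per-image
provenance through :class:`DatasetManifest`.

Coordinate convention, used everywhere in the package: arrays are indexed
``(row, col)``, 0-based, origin at the top-left; crops are half-open.
Intensities are promoted to float64 on load because downstream LoG
responses are signed and fractional.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RasterImage",
    "Volume",
    "ManifestRecord",
    "DatasetManifest",
    "load_volume",
    "load_raster",
    "volume_to_slices",
    "read_manifest",
    "write_manifest",
]

VALID_STAGES = (1, 2, 3, 4)


@dataclass(frozen=True)
class RasterImage:
    """A 2D grayscale image: the unit of filtering, clustering and training.

    Parameters
    ----------
    pixels
        2D float array of finite intensities, shape ``(height, width)``.
    spacing
        Optional ``(row_mm, col_mm)`` physical pixel size.
    source_id
        Free-form provenance string (file path, slice index, ...).
    """

    pixels: np.ndarray
    spacing: tuple[float, float] | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ValueError(f"pixels must be a non-empty 2D array, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels contain non-finite values")
        if self.spacing is not None:
            if len(self.spacing) != 2 or any(s <= 0 for s in self.spacing):
                raise ValueError(f"spacing must be two positive reals, got {self.spacing}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class Volume:
    """A 3D intensity grid with axes ``(slice, row, col)``."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        vx = np.asarray(self.voxels, dtype=np.float64)
        if vx.ndim != 3:
            raise ValueError(f"voxels must be 3D (slice, row, col), got shape {vx.shape}")
        if vx.shape[0] < 1:
            raise ValueError("volume must contain at least one slice")
        if not np.all(np.isfinite(vx)):
            raise ValueError("voxels contain non-finite values")
        object.__setattr__(self, "voxels", vx)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass(frozen=True)
class ManifestRecord:
    path: str
    label: int | None  # T stage in {1,2,3,4}, None = unlabeled
    patient_id: str


@dataclass
class DatasetManifest:
    """Maps image paths to optional T-stage labels and patient ids."""

    records: list[ManifestRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        paths = [r.path for r in self.records]
        if len(set(paths)) != len(paths):
            dupes = sorted({p for p in paths if paths.count(p) > 1})
            raise ValueError(f"duplicate image paths in manifest: {dupes}")
        for r in self.records:
            if r.label is not None and r.label not in VALID_STAGES:
                raise ValueError(f"label {r.label!r} for {r.path} not in {VALID_STAGES}")

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DatasetManifest):
            return NotImplemented
        return self.records == other.records

    @property
    def labeled(self) -> list[ManifestRecord]:
        return [r for r in self.records if r.label is not None]

    @property
    def unlabeled(self) -> list[ManifestRecord]:
        return [r for r in self.records if r.label is None]

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]


def load_volume(path: str | os.PathLike, format: str = "nifti") -> Volume:
    """Load a 3D volume from a NIfTI file or a DICOM series directory.

    Intensities are returned as stored (no rescale beyond the format's own
    slope/intercept).  DICOM slices are ordered by slice location, ties
    broken by instance number, so slice order is deterministic.
    """
    path = Path(path)
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom_dir":
        return _load_dicom_dir(path)
    raise ValueError(f"unknown volume format {format!r}; expected 'nifti' or 'dicom_dir'")


def _load_nifti(path: Path) -> Volume:
    import nibabel as nib

    if not path.exists():
        raise FileNotFoundError(f"NIfTI file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of error types
        raise ValueError(f"could not parse {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI payload, got {data.ndim}D in {path}")
    zooms = img.header.get_zooms()[:3]
    spacing = tuple(float(z) for z in zooms) if all(z > 0 for z in zooms) else None
    # nibabel axes are (i, j, k) with k the slice axis; move slices first.
    vox = np.moveaxis(data, 2, 0)
    return Volume(vox, spacing=spacing, source_id=str(path))


def _load_dicom_dir(path: Path) -> Volume:
    import pydicom

    if not path.is_dir():
        raise FileNotFoundError(f"DICOM directory not found: {path}")
    datasets = []
    for f in sorted(path.iterdir()):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue  # non-DICOM clutter is tolerated
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise ValueError(f"no readable DICOM slices in {path}")

    def sort_key(ds):
        loc = getattr(ds, "SliceLocation", None)
        if loc is None:
            ipp = getattr(ds, "ImagePositionPatient", None)
            loc = float(ipp[2]) if ipp is not None else 0.0
        return (float(loc), int(getattr(ds, "InstanceNumber", 0)))

    datasets.sort(key=sort_key)
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + inter)
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
    ps = getattr(datasets[0], "PixelSpacing", None)
    st = getattr(datasets[0], "SliceThickness", None)
    spacing = None
    if ps is not None and st is not None:
        spacing = (float(st), float(ps[0]), float(ps[1]))
    return Volume(np.stack(slices), spacing=spacing, source_id=str(path))


def load_raster(path: str | os.PathLike) -> RasterImage:
    """Load an 8- or 16-bit grayscale PNG (or any PIL-readable raster)."""
    from PIL import Image

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    with Image.open(str(path)) as im:
        if im.mode not in ("L", "I", "I;16", "F"):
            im = im.convert("L")
        arr = np.asarray(im, dtype=np.float64)
    return RasterImage(arr, source_id=str(path))


def volume_to_slices(
    v: Volume, plane: str = "axial", normalize: str = "none"
) -> list[RasterImage]:
    """Split a volume into per-slice :class:`RasterImage` objects.

    ``normalize='minmax'`` maps each slice affinely onto [0, 1]; a constant
    slice maps to all-zeros (there is no contrast to stretch).
    """
    if plane != "axial":
        raise ValueError(f"only the axial plane is supported, got {plane!r}")
    if normalize not in ("none", "minmax"):
        raise ValueError(f"normalize must be 'none' or 'minmax', got {normalize!r}")
    spacing = v.spacing[1:] if v.spacing is not None else None
    out = []
    for i in range(v.n_slices):
        sl = v.voxels[i]
        if normalize == "minmax":
            lo, hi = sl.min(), sl.max()
            sl = np.zeros_like(sl) if hi == lo else (sl - lo) / (hi - lo)
        out.append(RasterImage(sl, spacing=spacing, source_id=f"{v.source_id}[{i}]"))
    return out


def read_manifest(path: str | os.PathLike) -> DatasetManifest:
    """Read a ``path,label,patient_id`` CSV; blank label means unlabeled."""
    df = pd.read_csv(path, dtype={"path": str, "patient_id": str})
    missing = {"path", "label", "patient_id"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        raw = row["label"]
        if pd.isna(raw) or (isinstance(raw, str) and raw.strip() == ""):
            label = None
        else:
            try:
                label = int(raw)
            except (TypeError, ValueError):
                raise ValueError(f"non-integer label {raw!r} for {row['path']}")
        pid = "" if pd.isna(row["patient_id"]) else str(row["patient_id"])
        records.append(ManifestRecord(path=str(row["path"]), label=label, patient_id=pid))
    return DatasetManifest(records)


def write_manifest(m: DatasetManifest, path: str | os.PathLike) -> Path:
    """Write a manifest CSV; inverse of :func:`read_manifest`."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "path": [r.path for r in m.records],
            "label": ["" if r.label is None else r.label for r in m.records],
            "patient_id": [r.patient_id for r in m.records],
        }
    )
    df.to_csv(path, index=False)
    return path


def stack_pixels(images: Sequence[RasterImage]) -> np.ndarray:
    """Stack equally sized images into an ``(N, H, W)`` float array."""
    shapes = {im.shape for im in images}
    if len(shapes) != 1:
        raise ValueError(f"images have mixed shapes: {sorted(shapes)}")
    return np.stack([im.pixels for im in images])
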