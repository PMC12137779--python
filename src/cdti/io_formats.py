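"""Readers, writers and container types for the on-disk formats the pipeline touches.

Conventions fixed here and relied on everywhere else:

* image arrays are ``(n_frames, n_rows, n_cols)`` float; the **row** axis is
  the head-foot direction of a short-axis acquisition (anterior toward
  inferior), which is the dominant axis of respiratory motion;
* pixel coordinates are 0-based ``(row, col)``;
* a diffusion series on disk is one 3-D NIfTI file (rows x cols x frames) or a
  directory of 2-D NIfTI files, plus a sidecar CSV with one row per frame
  (columns ``b_value, direction_index, average_index, acquisition_order``);
* diffusion schemes use the FSL bval/bvec dialect, direction components in
  image-frame coordinates (row, col, slice-normal);
* LV contours are a JSON object ``{"endo": [[r, c], ...], "epi": [...]}``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

__all__ = [
    "ImageSeries",
    "DiffusionScheme",
    "ContourSet",
    "FormatError",
    "MetadataError",
    "read_series",
    "write_series",
    "read_scheme",
    "write_scheme",
    "read_contours",
    "write_contours",
    "write_maps",
    "read_map",
]

META_COLUMNS = ("b_value", "direction_index", "average_index", "acquisition_order")


class FormatError(ValueError):
    """Raised when a file's structure does not match the expected format."""


class MetadataError(ValueError):
    """Raised when frame metadata is inconsistent with the image data."""


@dataclass
class ImageSeries:
    """An ordered stack of 2-D magnitude frames from one slice location.

    Parameters
    ----------
    frames:
        ``(n_frames, n_rows, n_cols)`` float array of magnitude images.
    pixel_spacing_mm:
        ``(row_mm, col_mm)`` in-plane pixel spacing.
    frame_meta:
        One row per frame with columns ``b_value`` (s/mm^2),
        ``direction_index``, ``average_index`` (both 0-based) and
        ``acquisition_order``.  Rows are aligned with ``frames`` and sorted by
        acquisition order.
    slice_index:
        Slice location index within a multi-slice study.
    """

    frames: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    frame_meta: pd.DataFrame
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise FormatError(
                f"frames must be (n_frames, n_rows, n_cols), got shape {self.frames.shape}"
            )
        self.pixel_spacing_mm = (
            float(self.pixel_spacing_mm[0]),
            float(self.pixel_spacing_mm[1]),
        )
        meta = self.frame_meta.reset_index(drop=True)
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise MetadataError(f"frame_meta missing columns {missing}")
        if len(meta) != self.n_frames:
            raise MetadataError(
                f"frame_meta has {len(meta)} rows for {self.n_frames} frames"
            )
        order = meta["acquisition_order"].to_numpy()
        if sorted(order.tolist()) != list(range(self.n_frames)):
            raise MetadataError(
                "acquisition_order must be a permutation of 0..n_frames-1 (ties are illegal)"
            )
        n_b = meta["b_value"].nunique()
        if n_b > 2:
            raise MetadataError(
                f"series carries {n_b} distinct b-values; at most two shells are supported"
            )
        # canonical ordering: frames sorted by acquisition order
        if not np.array_equal(order, np.arange(self.n_frames)):
            idx = np.argsort(order, kind="stable")
            self.frames = self.frames[idx]
            meta = meta.iloc[idx].reset_index(drop=True)
        self.frame_meta = meta

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def b_values(self) -> np.ndarray:
        return self.frame_meta["b_value"].to_numpy(dtype=float)

    @property
    def low_b(self) -> float:
        return float(self.frame_meta["b_value"].min())

    @property
    def high_b(self) -> float:
        return float(self.frame_meta["b_value"].max())

    def with_frames(self, frames: np.ndarray) -> "ImageSeries":
        """Return a copy carrying new pixel data with identical metadata."""
        return replace(self, frames=np.asarray(frames, float), frame_meta=self.frame_meta.copy())

    def subset(self, index: np.ndarray) -> "ImageSeries":
        """Select frames by boolean or integer index, renumbering acquisition order."""
        frames = self.frames[index]
        meta = self.frame_meta.iloc[np.arange(self.n_frames)[index]].reset_index(drop=True)
        meta = meta.copy()
        meta["acquisition_order"] = np.arange(len(meta))
        return ImageSeries(frames, self.pixel_spacing_mm, meta, self.slice_index)


@dataclass
class DiffusionScheme:
    """Per-measurement b-values and unit gradient directions.

    ``directions`` are expressed in image-frame coordinates
    (row, col, slice-normal); zero-norm entries denote pure b0 measurements
    and are flagged in ``is_b0``.
    """

    b_values: np.ndarray
    directions: np.ndarray
    is_b0: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=float).ravel()
        self.directions = np.asarray(self.directions, dtype=float).reshape(-1, 3)
        if len(self.b_values) != len(self.directions):
            raise FormatError(
                f"{len(self.b_values)} b-values but {len(self.directions)} directions"
            )
        norms = np.linalg.norm(self.directions, axis=1)
        if self.is_b0 is None:
            self.is_b0 = norms < 1e-12
        self.is_b0 = np.asarray(self.is_b0, bool).ravel()
        bad = ~self.is_b0 & (np.abs(norms - 1.0) > 1e-6)
        if bad.any():
            raise FormatError("non-b0 directions must have unit norm")

    def __len__(self) -> int:
        return len(self.b_values)


@dataclass
class ContourSet:
    """Ordered endocardial and epicardial contours of the left ventricle."""

    endo: np.ndarray  # (n, 2) float, (row, col)
    epi: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        self.endo = np.asarray(self.endo, float).reshape(-1, 2)
        self.epi = np.asarray(self.epi, float).reshape(-1, 2)
        for name, c in (("endo", self.endo), ("epi", self.epi)):
            if len(c) < 8:
                raise FormatError(f"{name} contour needs >= 8 points, got {len(c)}")
        epi_poly = Polygon(self.epi)
        if not epi_poly.is_valid:
            raise FormatError("epi contour is self-intersecting")
        for p in self.endo:
            if not epi_poly.contains(Point(p)):
                raise FormatError("epi contour must enclose every endo point")


# ---------------------------------------------------------------------------
# series I/O


def _load_frames(path: Path) -> tuple[np.ndarray, tuple[float, float]]:
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix in (".nii", ".gz") or p.name.endswith(".nii.gz"))
        if not files:
            raise FormatError(f"no NIfTI files in directory {path}")
        frames, spacing, shape = [], None, None
        for f in files:
            img = nib.load(str(f))
            arr = np.asarray(img.dataobj, dtype=np.float64)
            if arr.ndim == 3 and arr.shape[2] == 1:
                arr = arr[:, :, 0]
            if arr.ndim != 2:
                raise FormatError(f"{f.name}: expected a 2-D frame, got shape {arr.shape}")
            if shape is None:
                shape = arr.shape
                zooms = img.header.get_zooms()
                spacing = (float(zooms[0]), float(zooms[1]))
            elif arr.shape != shape:
                raise FormatError(
                    f"{f.name}: frame shape {arr.shape} differs from {shape}"
                )
            frames.append(arr)
        return np.stack(frames), spacing  # type: ignore[return-value]
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected rows x cols x frames, got shape {arr.shape}")
    zooms = img.header.get_zooms()
    return np.moveaxis(arr, 2, 0), (float(zooms[0]), float(zooms[1]))


def read_series(path: str | Path, meta_path: str | Path, slice_index: int = 0) -> ImageSeries:
    """Load an :class:`ImageSeries` from NIfTI data plus a sidecar metadata CSV.

    ``path`` is either a 3-D NIfTI file whose third axis is frames, or a
    directory of 2-D NIfTI files (stacked in filename order).  Frames are
    reordered by ``acquisition_order`` on load.
    """
    frames, spacing = _load_frames(Path(path))
    meta = pd.read_csv(meta_path)
    return ImageSeries(frames, spacing, meta, slice_index=slice_index)


def write_series(series: ImageSeries, path: str | Path, meta_path: str | Path) -> None:
    """Write a series as one 3-D NIfTI (float32) plus the metadata CSV."""
    data = np.moveaxis(series.frames.astype(np.float32), 0, 2)
    affine = np.diag([series.pixel_spacing_mm[0], series.pixel_spacing_mm[1], 1.0, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((series.pixel_spacing_mm[0], series.pixel_spacing_mm[1], 1.0))
    nib.save(img, str(path))
    series.frame_meta.to_csv(meta_path, index=False)


# ---------------------------------------------------------------------------
# scheme I/O (FSL bval/bvec dialect)


def read_scheme(bval_path: str | Path, bvec_path: str | Path) -> DiffusionScheme:
    """Parse FSL-dialect bval/bvec files into a :class:`DiffusionScheme`.

    Zero-norm bvec columns are kept as ``(0, 0, 0)`` and flagged ``is_b0``;
    all other columns are normalized to unit length.
    """
    bvals = np.loadtxt(bval_path, ndmin=2).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] != 3:
        raise FormatError(f"bvec file must have 3 rows (x, y, z), got {bvecs.shape[0]}")
    if bvecs.shape[1] != len(bvals):
        raise FormatError(
            f"bval has {len(bvals)} entries but bvec has {bvecs.shape[1]} columns"
        )
    directions = bvecs.T.astype(float)
    norms = np.linalg.norm(directions, axis=1)
    is_b0 = norms < 1e-12
    directions[~is_b0] /= norms[~is_b0, None]
    directions[is_b0] = 0.0
    return DiffusionScheme(bvals, directions, is_b0)


def write_scheme(scheme: DiffusionScheme, bval_path: str | Path, bvec_path: str | Path) -> None:
    np.savetxt(bval_path, scheme.b_values[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.8f")


# ---------------------------------------------------------------------------
# contour I/O


def read_contours(path: str | Path) -> ContourSet:
    with open(path) as fh:
        obj = json.load(fh)
    return ContourSet(np.asarray(obj["endo"]), np.asarray(obj["epi"]), obj.get("closed", True))


def write_contours(contours: ContourSet, path: str | Path) -> None:
    obj = {
        "endo": np.asarray(contours.endo, float).tolist(),
        "epi": np.asarray(contours.epi, float).tolist(),
        "closed": bool(contours.closed),
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)


# ---------------------------------------------------------------------------
# scalar map I/O


def write_maps(
    maps: dict[str, np.ndarray],
    out_dir: str | Path,
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0),
    prefix: str = "",
) -> dict[str, Path]:
    """Write named 2-D scalar maps as float32 NIfTI files.

    All maps must share one shape.  NaN values (pixels outside the LV mask)
    are preserved.  A map without a single finite value is still written, with
    a warning.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    shapes = {np.asarray(m).shape for m in maps.values()}
    if len(shapes) > 1:
        raise FormatError(f"maps have mismatched shapes: {sorted(shapes)}")
    affine = np.diag([pixel_spacing_mm[0], pixel_spacing_mm[1], 1.0, 1.0])
    written: dict[str, Path] = {}
    for name, arr in maps.items():
        arr = np.asarray(arr, dtype=np.float32)
        if not np.isfinite(arr).any():
            warnings.warn(f"map '{name}' has no finite values; writing anyway")
        img = nib.Nifti1Image(arr, affine)
        img.header.set_zooms((pixel_spacing_mm[0], pixel_spacing_mm[1]))
        p = out_dir / f"{prefix}{name}.nii"
        nib.save(img, str(p))
        written[name] = p
    return written


def read_map(path: str | Path) -> tuple[np.ndarray, tuple[float, float]]:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    zooms = img.header.get_zooms()
    return arr, (float(zooms[0]), float(zooms[1]))
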