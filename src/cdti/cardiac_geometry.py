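"""LV coordinate frame, helix-angle map, helix-angle transmurality, ROI summaries.

The short-axis left-ventricular wall is described by a local orthonormal
frame per pixel: ``rad`` (in-plane outward radial), ``long`` (slice normal)
and ``circ = long x rad`` (in-plane circumferential), a right-handed triad.
Transmural depth runs 0% at the endocardium to 100% at the epicardium, by
two-distance normalization ``100 * d_endo / (d_endo + d_epi)``.

Helix angle (HA) is the signed angle, within the circ-long wall-tangent
plane, between the circumferential direction and the projection of the
primary diffusion eigenvector onto that plane; healthy myocardium runs from
positive (left-handed helix, endo) to negative (right-handed, epi).  Helix
angle transmurality (HAT) summarizes that slope in degrees per percent depth:
the wall is split into equal angular sectors about the LV centroid, HA is
regressed on depth by ordinary least squares within each sector, and the
global HAT is the mean of the sector slopes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from skimage.draw import polygon2mask

from .io_formats import ContourSet

logger = logging.getLogger(__name__)

__all__ = [
    "LVGeometry",
    "build_geometry",
    "helix_angle",
    "hat",
    "summarize",
]

MIN_SECTOR_PIXELS = 10
PROJECTION_NORM_MIN = 0.2


@dataclass
class LVGeometry:
    """Per-pixel LV wall coordinate system on one slice.

    ``depth`` is transmural depth in percent (0 endo, 100 epi); ``circ``,
    ``long`` and ``rad`` are unit 3-vector maps (shape ``(n_rows, n_cols, 3)``)
    forming a right-handed orthonormal triad inside ``mask``.
    """

    mask: np.ndarray
    depth: np.ndarray
    circ: np.ndarray
    long: np.ndarray
    rad: np.ndarray
    centroid: tuple[float, float] = (0.0, 0.0)
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        d = self.depth[self.mask]
        if d.size and (np.nanmin(d) < -1e-9 or np.nanmax(d) > 100 + 1e-9):
            raise ValueError("depth must lie in [0, 100] inside the mask")


def _resample_contour(points: np.ndarray, step_px: float = 0.25) -> np.ndarray:
    """Densely resample a closed polygon boundary at ~step_px spacing."""
    pts = np.asarray(points, float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    n = max(int(np.ceil(total / step_px)), 32)
    ti = np.linspace(0.0, total, n, endpoint=False)
    fr = interp1d(t, closed[:, 0])
    fc = interp1d(t, closed[:, 1])
    return np.column_stack([fr(ti), fc(ti)])


def build_geometry(
    contours: ContourSet,
    shape: tuple[int, int],
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0),
) -> LVGeometry:
    """Rasterize LV contours into mask, transmural depth and local frame.

    The wall mask is the set of pixels inside the epicardial polygon and
    outside the endocardial one.  Depth uses Euclidean distances to the two
    (densely resampled) contours; the radial direction follows the gradient
    of the signed distance difference, lightly smoothed.
    """
    endo_poly = Polygon(contours.endo)
    epi_poly = Polygon(contours.epi)
    if not endo_poly.is_valid or not epi_poly.is_valid:
        raise ValueError("contours are self-intersecting")
    if epi_poly.intersects(endo_poly.exterior) and not epi_poly.contains(endo_poly):
        raise ValueError("endo and epi contours cross")

    epi_mask = polygon2mask(shape, contours.epi)
    endo_mask = polygon2mask(shape, contours.endo)
    mask = epi_mask & ~endo_mask

    endo_pts = _resample_contour(contours.endo)
    epi_pts = _resample_contour(contours.epi)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    pix = np.column_stack([rr.ravel(), cc.ravel()])
    d_endo = cKDTree(endo_pts).query(pix)[0].reshape(shape)
    d_epi = cKDTree(epi_pts).query(pix)[0].reshape(shape)

    depth = np.full(shape, np.nan)
    denom = d_endo + d_epi
    with np.errstate(invalid="ignore", divide="ignore"):
        depth_all = 100.0 * d_endo / np.where(denom > 0, denom, 1.0)
    depth[mask] = np.clip(depth_all[mask], 0.0, 100.0)

    # radial = gradient of the signed wall coordinate (negative inside endo)
    inside_endo = endo_mask
    phi = np.where(inside_endo, -d_endo, d_endo)
    phi = gaussian_filter(phi, 1.0, mode="nearest")
    gr, gc = np.gradient(phi)
    norm = np.hypot(gr, gc)
    # fall back to centroid-radial direction where the gradient is degenerate
    centroid = (float(rr[mask].mean()), float(cc[mask].mean())) if mask.any() else (0.0, 0.0)
    fr, fc = rr - centroid[0], cc - centroid[1]
    fnorm = np.hypot(fr, fc)
    use_fallback = norm < 1e-6
    gr = np.where(use_fallback, np.where(fnorm > 0, fr / np.maximum(fnorm, 1e-12), 1.0), gr)
    gc = np.where(use_fallback, np.where(fnorm > 0, fc / np.maximum(fnorm, 1e-12), 0.0), gc)
    norm = np.hypot(gr, gc)
    ur, uc = gr / norm, gc / norm

    rad = np.stack([ur, uc, np.zeros(shape)], axis=-1)
    longv = np.zeros((*shape, 3))
    longv[..., 2] = 1.0
    circ = np.stack([-uc, ur, np.zeros(shape)], axis=-1)  # long x rad
    return LVGeometry(mask, depth, circ, longv, rad, centroid, tuple(pixel_spacing_mm))


def helix_angle(primary: np.ndarray, geom: LVGeometry) -> np.ndarray:
    """Helix-angle map in degrees from a primary-eigenvector map.

    The eigenvector is projected onto the wall-tangent (circ-long) plane;
    its sign is fixed so the circumferential component is non-negative,
    making HA single-valued in (-90, 90].  Pixels whose tangent-plane
    projection norm falls below 0.2 (fiber nearly radial or undefined) are
    masked out as NaN.
    """
    primary = np.asarray(primary, float)
    if primary.shape != (*geom.mask.shape, 3):
        raise ValueError("primary must be an (n_rows, n_cols, 3) vector map")
    comp_c = np.einsum("...i,...i->...", primary, geom.circ)
    comp_l = np.einsum("...i,...i->...", primary, geom.long)
    flip = comp_c < 0
    comp_c = np.where(flip, -comp_c, comp_c)
    comp_l = np.where(flip, -comp_l, comp_l)
    proj = np.hypot(comp_c, comp_l)
    ha = np.degrees(np.arctan2(comp_l, comp_c))
    ha = np.where(geom.mask & (proj >= PROJECTION_NORM_MIN), ha, np.nan)
    return ha


def _sector_labels(geom: LVGeometry, n_sectors: int) -> np.ndarray:
    rr, cc = np.mgrid[0 : geom.mask.shape[0], 0 : geom.mask.shape[1]].astype(float)
    theta = np.arctan2(cc - geom.centroid[1], rr - geom.centroid[0])  # (-pi, pi]
    return np.floor((theta + np.pi) / (2 * np.pi / n_sectors)).astype(int) % n_sectors


def hat(
    ha_map: np.ndarray, geom: LVGeometry, n_sectors: int = 6
) -> tuple[float, np.ndarray]:
    """Helix-angle transmurality in degrees per percent depth.

    Returns ``(global_hat, sector_slopes)`` where ``sector_slopes`` has one
    OLS slope of HA against depth per angular sector (NaN where a sector has
    fewer than 10 valid pixels; such sectors are excluded from the mean).
    """
    ha_map = np.asarray(ha_map, float)
    labels = _sector_labels(geom, n_sectors)
    slopes = np.full(n_sectors, np.nan)
    valid = geom.mask & np.isfinite(ha_map) & np.isfinite(geom.depth)
    for s in range(n_sectors):
        sel = valid & (labels == s)
        n = int(sel.sum())
        if n < MIN_SECTOR_PIXELS:
            logger.warning("sector %d has %d valid pixels (<%d); slope set NaN",
                           s, n, MIN_SECTOR_PIXELS)
            continue
        x = geom.depth[sel]
        yv = ha_map[sel]
        if np.ptp(x) < 1e-9:
            continue
        slopes[s] = np.polyfit(x, yv, 1)[0]
    global_hat = float(np.nanmean(slopes)) if np.isfinite(slopes).any() else float("nan")
    return global_hat, slopes


def summarize(
    maps_per_slice: list[dict[str, float | np.ndarray]],
    geoms: list[LVGeometry] | None = None,
) -> pd.DataFrame:
    """Per-slice and global mean/SD table for named maps or scalar statistics.

    Each entry of ``maps_per_slice`` maps a name to either a 2-D map
    (averaged over the matching geometry mask, population SD) or an already
    scalar value (SD recorded as NaN).  The global row per name is the
    arithmetic mean of the per-slice means.
    """
    rows = []
    for i, maps in enumerate(maps_per_slice):
        geom = geoms[i] if geoms is not None else None
        for name, m in maps.items():
            if np.isscalar(m) or np.asarray(m).ndim == 0:
                mean, sd = float(m), float("nan")
            else:
                arr = np.asarray(m, float)
                sel = np.isfinite(arr)
                if geom is not None:
                    sel &= geom.mask
                vals = arr[sel]
                mean = float(vals.mean()) if vals.size else float("nan")
                sd = float(vals.std()) if vals.size else float("nan")  # population SD
            rows.append({"slice": i, "map": name, "mean": mean, "sd": sd})
    df = pd.DataFrame(rows)
    for name in df["map"].unique():
        sub = df[df["map"] == name]
        rows.append({
            "slice": "global",
            "map": name,
            "mean": float(sub["mean"].mean()),
            "sd": float(sub["mean"].std(ddof=0)),
        })
    return pd.DataFrame(rows)
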