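"""Interpolation and diffusion-tensor estimation (MD, FA, principal direction).

Model: ``ln S = ln S0 - b g^T D g`` with b in s/mm^2 and D in um^2/ms, so the
exponent uses ``b/1000``.  The fit is linear least squares on log-signal: an
ordinary pass for initialization followed by one weighted pass with weights
equal to the squared predicted signals, which undoes the noise-amplification
of the log transform at low signal.  Low-b (b = 50) frames are treated as
diffusion-weighted measurements with their own encoding directions, not as
pure b0 — at b = 50 the encoding attenuation is small but not zero, and the
two-shell design uses it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .io_formats import ImageSeries, DiffusionScheme

__all__ = [
    "TensorField",
    "interpolate_series",
    "interpolate_frame",
    "fit_tensor",
    "design_matrix",
    "tensors_to_matrices",
    "md",
    "fa",
    "principal_direction",
]

# order of the 6 unique tensor elements in packed storage
TENSOR_ELEMENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")

SIGNAL_FLOOR_REL = 1e-6  # exclusion floor as fraction of per-frame max signal


@dataclass
class TensorField:
    """Per-pixel symmetric diffusion tensor over a mask.

    ``tensors`` has shape ``(n_rows, n_cols, 6)`` holding
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) in um^2/ms; ``s0`` is the non-DW signal
    estimate; ``mask`` marks pixels with a valid fit.  Axes x, y, z are the
    image row, col and slice-normal directions.
    """

    tensors: np.ndarray
    s0: np.ndarray
    mask: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, float)
        self.s0 = np.asarray(self.s0, float)
        self.mask = np.asarray(self.mask, bool)
        if self.tensors.shape != (*self.mask.shape, 6):
            raise ValueError("tensors must be (n_rows, n_cols, 6) matching mask")
        if not np.isfinite(self.tensors[self.mask]).all():
            raise ValueError("tensors must be finite inside the mask")

    @property
    def matrices(self) -> np.ndarray:
        """Tensors as ``(n_rows, n_cols, 3, 3)`` symmetric matrices."""
        return tensors_to_matrices(self.tensors)


def tensors_to_matrices(packed: np.ndarray) -> np.ndarray:
    """Expand packed 6-element tensors (...,6) into symmetric (...,3,3)."""
    packed = np.asarray(packed, float)
    out = np.empty(packed.shape[:-1] + (3, 3), float)
    dxx, dyy, dzz, dxy, dxz, dyz = (packed[..., i] for i in range(6))
    out[..., 0, 0] = dxx
    out[..., 1, 1] = dyy
    out[..., 2, 2] = dzz
    out[..., 0, 1] = out[..., 1, 0] = dxy
    out[..., 0, 2] = out[..., 2, 0] = dxz
    out[..., 1, 2] = out[..., 2, 1] = dyz
    return out


# ---------------------------------------------------------------------------
# interpolation


def _target_shape(
    shape: tuple[int, int],
    spacing: tuple[float, float],
    target: tuple[float, float],
) -> tuple[int, int]:
    return (
        int(np.ceil(shape[0] * spacing[0] / target[0])),
        int(np.ceil(shape[1] * spacing[1] / target[1])),
    )


def interpolate_frame(
    frame: np.ndarray,
    spacing: tuple[float, float],
    target_spacing: tuple[float, float],
) -> tuple[np.ndarray, tuple[float, float]]:
    """Cubic-spline resample of one frame to (approximately) a target spacing.

    The output grid has ``ceil(n * spacing / target)`` pixels per axis and the
    returned spacing is the exact spacing of that grid (field of view is
    preserved), e.g. 48 cols at 2.7 mm -> 93 cols at 1.394 mm.
    """
    if tuple(spacing) == tuple(target_spacing):
        return np.asarray(frame, float).copy(), tuple(spacing)
    new_shape = _target_shape(frame.shape, spacing, target_spacing)
    out = resize(np.asarray(frame, float), new_shape, order=3, mode="edge",
                 anti_aliasing=False)
    new_spacing = (
        frame.shape[0] * spacing[0] / new_shape[0],
        frame.shape[1] * spacing[1] / new_shape[1],
    )
    return out, new_spacing


def interpolate_series(
    series: ImageSeries, target_spacing_mm: tuple[float, float] = (1.4, 1.4)
) -> ImageSeries:
    """Resample every frame of a series to the map-resolution grid (default 1.4 mm)."""
    if tuple(series.pixel_spacing_mm) == tuple(target_spacing_mm):
        return series.with_frames(series.frames.copy())
    frames = []
    new_spacing = series.pixel_spacing_mm
    for f in series.frames:
        out, new_spacing = interpolate_frame(f, series.pixel_spacing_mm, target_spacing_mm)
        frames.append(out)
    return ImageSeries(
        np.stack(frames), new_spacing, series.frame_meta.copy(), series.slice_index
    )


# ---------------------------------------------------------------------------
# tensor fit


def design_matrix(scheme: DiffusionScheme) -> np.ndarray:
    """Log-linear design: columns (1, -b'gx^2, -b'gy^2, -b'gz^2, -2b'gxgy, -2b'gxgz, -2b'gygz).

    ``b' = b/1000`` so the tensor solution comes out in um^2/ms.
    """
    b = scheme.b_values / 1000.0
    g = scheme.directions
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack([
        np.ones_like(b),
        -b * gx * gx,
        -b * gy * gy,
        -b * gz * gz,
        -2 * b * gx * gy,
        -2 * b * gx * gz,
        -2 * b * gy * gz,
    ])


def _check_design(scheme: DiffusionScheme) -> np.ndarray:
    X = design_matrix(scheme)
    if X.shape[0] < 7:
        raise ValueError(
            f"tensor fit needs >= 7 measurements, got {X.shape[0]}"
        )
    if np.linalg.matrix_rank(X) < 7:
        # identify directions that do not extend the span
        uniq = np.unique(np.round(np.abs(scheme.directions), 6), axis=0)
        raise ValueError(
            "diffusion scheme is rank-deficient (needs >= 6 non-collinear "
            f"directions over the shells); distinct |directions|: {len(uniq)}"
        )
    return X


def fit_tensor(
    averaged: ImageSeries,
    scheme: DiffusionScheme,
    mask: np.ndarray | None = None,
) -> TensorField:
    """Per-pixel weighted linear least-squares tensor fit.

    ``averaged`` supplies one frame per measurement of ``scheme`` (same
    order).  Signals at or below ``1e-6 x`` the frame maximum are excluded
    per pixel; pixels with fewer than 7 usable measurements are dropped from
    the output mask with NaN tensors.
    """
    X = _check_design(scheme)
    n_meas = X.shape[0]
    if averaged.n_frames != n_meas:
        raise ValueError(
            f"series has {averaged.n_frames} frames but scheme has {n_meas} measurements"
        )
    shape = averaged.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, bool)
    if mask.shape != shape:
        raise ValueError("mask shape must match frame shape")

    S = averaged.frames.reshape(n_meas, -1).T[mask.ravel()]  # (n_pix, n_meas)
    floor = SIGNAL_FLOOR_REL * averaged.frames.max()
    valid = S > max(floor, 0.0)
    n_valid = valid.sum(axis=1)
    fit_ok = n_valid >= 7

    # per-pixel intensity normalization keeps the log well-conditioned
    S_safe = np.where(valid, S, 1.0)
    scale = np.where(fit_ok, S_safe.max(axis=1, where=valid, initial=1e-30), 1.0)
    y = np.log(np.where(valid, S_safe / scale[:, None], 1.0))

    def wls(weights: np.ndarray) -> np.ndarray:
        # weights: (n_pix, n_meas) >= 0 with exclusions already zeroed
        A = np.einsum("mi,pm,mj->pij", X, weights, X, optimize=True)
        rhs = np.einsum("mi,pm,pm->pi", X, weights, y, optimize=True)
        A[~fit_ok] = np.eye(7)
        rhs[~fit_ok] = 0.0
        return np.linalg.solve(A, rhs[..., None])[..., 0]

    beta = wls(valid.astype(float))
    pred = X @ beta.T  # (n_meas, n_pix) predicted log-signal
    w = valid.astype(float) * np.exp(2.0 * pred.T)
    beta = wls(w)

    tensors = np.full((*shape, 6), np.nan)
    s0 = np.full(shape, np.nan)
    out_mask = np.zeros(shape, dtype=bool)
    idx = np.flatnonzero(mask.ravel())
    ok_idx = idx[fit_ok]
    flat_t = tensors.reshape(-1, 6)
    flat_t[ok_idx] = beta[fit_ok, 1:]
    s0.ravel()[ok_idx] = np.exp(beta[fit_ok, 0]) * scale[fit_ok]
    out_mask.ravel()[ok_idx] = True
    return TensorField(tensors, s0, out_mask, averaged.pixel_spacing_mm)


# ---------------------------------------------------------------------------
# scalar invariants


def _eigvals(tensor: np.ndarray) -> np.ndarray:
    """Eigenvalues of (...,3,3) tensors, clipped at zero, descending order.

    Tensors with non-finite entries yield NaN eigenvalues.
    """
    t = np.asarray(tensor, float)
    finite = np.isfinite(t).all(axis=(-2, -1))
    vals = np.linalg.eigvalsh(np.where(finite[..., None, None], t, 0.0))
    vals = np.where(finite[..., None], vals, np.nan)
    return np.clip(vals[..., ::-1], 0.0, None)


def md(tensor: np.ndarray) -> np.ndarray | float:
    """Mean diffusivity: mean of the (non-negative-clipped) eigenvalues, um^2/ms."""
    out = _eigvals(tensor).mean(axis=-1)
    return float(out) if out.ndim == 0 else out

def fa(tensor: np.ndarray) -> np.ndarray | float:
    """Fractional anisotropy: sqrt(3/2) * ||lambda - MD|| / ||lambda||, in [0, 1]."""
    lam = _eigvals(tensor)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(lam - mean, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(1.5) * num / den
    out = np.where(den > 0, out, np.nan)
    return float(out) if out.ndim == 0 else out


def principal_direction(
    tensor: np.ndarray, degenerate_rtol: float = 1e-8
) -> np.ndarray:
    """Unit eigenvector of the largest eigenvalue of (...,3,3) tensors.

    The sign is provisionally fixed so the largest-magnitude component is
    positive (a deterministic stand-in; helix-angle mapping re-fixes it so
    the circumferential component is non-negative).  Pixels where the top
    two eigenvalues coincide within ``degenerate_rtol`` (relative) are
    degenerate and return NaN.
    """
    t = np.asarray(tensor, float)
    finite = np.isfinite(t).all(axis=(-2, -1))
    vals, vecs = np.linalg.eigh(np.where(finite[..., None, None], t, 0.0))
    v1 = vecs[..., :, -1]
    lam1, lam2 = vals[..., -1], vals[..., -2]
    degenerate = (lam1 - lam2) <= degenerate_rtol * np.maximum(np.abs(lam1), 1e-30)
    # deterministic provisional sign
    lead = np.argmax(np.abs(v1), axis=-1)
    sign = np.sign(np.take_along_axis(v1, lead[..., None], axis=-1))[..., 0]
    sign = np.where(sign == 0, 1.0, sign)
    v1 = v1 * sign[..., None]
    v1 = np.where(degenerate[..., None], np.nan, v1)
    return v1
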