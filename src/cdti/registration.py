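"""Pair-wise symmetric, inverse-consistent deformable 2-D registration.

The engine is a log-domain diffeomorphic demons scheme: a single stationary
velocity field ``v`` is optimized, and the forward/inverse displacement fields
are its group exponentials ``exp(v)`` / ``exp(-v)`` computed by scaling and
squaring.  Inverse consistency therefore holds by construction, up to the
numerical error of the exponential, and is certified a posteriori by
:func:`inverse_consistency_error`.

Similarity is local normalized cross-correlation with a Gaussian window:
both images are locally standardized (Gaussian local mean removed, divided by
Gaussian local standard deviation) and demons forces are computed on the
standardized intensities.  Minimizing the pointwise squared difference of two
locally z-scored images is equivalent to maximizing their windowed correlation
coefficient, so the forces tolerate the contrast difference between low-b and
high-b diffusion-weighted frames — no diffusion-contrast modeling is needed.

Field convention: a displacement field ``d`` maps points of its *own* grid
into the other image, and images are warped by pull-back,
``out(p) = img(p + d(p))``.  The ``forward`` field of a pair lives on the
fixed grid and resamples the moving image onto it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.transform import resize

logger = logging.getLogger(__name__)

__all__ = [
    "RegistrationParams",
    "DisplacementFieldPair",
    "register_pair",
    "warp",
    "compose",
    "field_exp",
    "inverse_consistency_error",
    "jacobian_determinant",
]

_BORDER_PX = 2  # forces zeroed on this margin (EPI frames carry tissue at FOV edges)


@dataclass
class RegistrationParams:
    """Tunable knobs of the demons engine.

    All length scales are in pixels of the registered images.

    ``n_levels`` / ``iters_per_level``
        Gaussian pyramid depth and fixed per-level iteration counts (no
        tolerance-based early exit, for determinism).
    ``sigma_fluid`` / ``sigma_diffusion``
        Gaussian smoothing of the per-iteration update (fluid-like) and of
        the accumulated velocity field (diffusion-like).
    ``lncc_window_sigma``
        Gaussian window of the local correlation similarity.
    ``n_squaring_steps``
        Scaling-and-squaring steps of the field exponential.
    ``step_scale``
        Multiplier on the demons update (max step ~0.5 * step_scale px).
    ``ic_tol``
        Mean inverse-consistency residual regarded as converged, px.
    """

    n_levels: int = 3
    iters_per_level: tuple[int, ...] = (80, 50, 25)
    sigma_fluid: float = 2.0
    sigma_diffusion: float = 5.0
    lncc_window_sigma: float = 2.0
    n_squaring_steps: int = 6
    step_scale: float = 1.0
    ic_tol: float = 0.1

    def __post_init__(self) -> None:
        self.iters_per_level = tuple(int(i) for i in self.iters_per_level)
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if len(self.iters_per_level) != self.n_levels:
            raise ValueError("iters_per_level must have n_levels entries")
        for name in ("sigma_fluid", "sigma_diffusion", "lncc_window_sigma",
                     "step_scale", "ic_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_squaring_steps < 1:
            raise ValueError("n_squaring_steps must be >= 1")


@dataclass
class DisplacementFieldPair:
    """Mutually inverse dense displacement fields of one registration.

    ``forward`` lives on the fixed grid and maps into the moving image;
    ``inverse`` lives on the moving grid and maps into the fixed image.
    Both are ``(2, n_rows, n_cols)`` arrays (row-, col-displacement, px).
    """

    forward: np.ndarray
    inverse: np.ndarray
    converged: bool = True
    final_similarity: float = dc_field(default=np.nan)

    def __post_init__(self) -> None:
        self.forward = np.ascontiguousarray(self.forward, dtype=np.float64)
        self.inverse = np.ascontiguousarray(self.inverse, dtype=np.float64)
        if self.forward.shape != self.inverse.shape or self.forward.shape[0] != 2:
            raise ValueError("fields must both be (2, n_rows, n_cols)")
        if not (np.isfinite(self.forward).all() and np.isfinite(self.inverse).all()):
            raise ValueError("displacement fields must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.forward.shape[1:]


def _grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    r = np.arange(shape[0], dtype=np.float64)[:, None]
    c = np.arange(shape[1], dtype=np.float64)[None, :]
    return np.broadcast_to(r, shape), np.broadcast_to(c, shape)


def warp(image: np.ndarray, field: np.ndarray, mode: str = "linear") -> np.ndarray:
    """Pull-back resampling: ``out(p) = image(p + field(p))``.

    ``mode`` is ``"linear"`` (order-1) or ``"nearest"`` (order-0, preserves
    label/mask values).  Out-of-bounds samples take the nearest edge value.
    """
    image = np.asarray(image, dtype=np.float64)
    field = np.asarray(field, dtype=np.float64)
    if field.shape != (2, *image.shape):
        raise ValueError(f"field shape {field.shape} does not match image {image.shape}")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    rr, cc = _grid(image.shape)
    order = 1 if mode == "linear" else 0
    return map_coordinates(
        image, [rr + field[0], cc + field[1]], order=order, mode="nearest"
    )


def compose(f: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Displacement of the composed map, ``(f o g)(p) = g(p) + f(p + g(p))``.

    Warping an image by the result equals warping by ``f`` then by ``g``
    (pull-back order).  ``f`` is sampled linearly with edge clamping.
    """
    f = np.asarray(f, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if f.shape != g.shape or f.shape[0] != 2:
        raise ValueError("fields must share shape (2, n_rows, n_cols)")
    rr, cc = _grid(f.shape[1:])
    coords = [rr + g[0], cc + g[1]]
    out = np.empty_like(g)
    out[0] = g[0] + map_coordinates(f[0], coords, order=1, mode="nearest")
    out[1] = g[1] + map_coordinates(f[1], coords, order=1, mode="nearest")
    return out


def field_exp(velocity: np.ndarray, n_steps: int = 6) -> np.ndarray:
    """Group exponential of a stationary velocity field by scaling and squaring."""
    d = np.asarray(velocity, dtype=np.float64) / float(2 ** n_steps)
    for _ in range(n_steps):
        d = compose(d, d)
    return d


def inverse_consistency_error(pair: DisplacementFieldPair) -> float:
    """Mean interior residual ``|forward o inverse|`` in pixels.

    The interior excludes a margin of the maximum displacement magnitude
    (edge-clamped sampling is meaningless there).
    """
    resid = compose(pair.forward, pair.inverse)
    m = max(1, int(np.ceil(max(np.abs(pair.forward).max(), np.abs(pair.inverse).max()))) + 1)
    nr, nc = pair.shape
    if 2 * m >= nr or 2 * m >= nc:
        m = 1
    core = resid[:, m : nr - m, m : nc - m]
    return float(np.mean(np.hypot(core[0], core[1])))


def jacobian_determinant(field: np.ndarray) -> np.ndarray:
    """Jacobian determinant map of the deformation ``p -> p + field(p)``."""
    drr, drc = np.gradient(field[0])
    dcr, dcc = np.gradient(field[1])
    return (1.0 + drr) * (1.0 + dcc) - drc * dcr


# ---------------------------------------------------------------------------
# demons internals


def _standardize(img: np.ndarray, sigma: float, eps: float) -> np.ndarray:
    """Gaussian local z-score: remove local mean, divide by local SD."""
    mean = gaussian_filter(img, sigma, mode="nearest")
    var = gaussian_filter(img * img, sigma, mode="nearest") - mean * mean
    return (img - mean) / np.sqrt(np.maximum(var, 0.0) + eps)


def _demons_update(fixed_n: np.ndarray, moving_n: np.ndarray) -> np.ndarray:
    """Symmetric-gradient demons step pulling ``moving_n`` toward ``fixed_n``.

    Both inputs are locally standardized images on one grid.  Per-pixel step
    norm is bounded by 1/2 px (standard demons normalization with the
    intensity-difference term in the denominator).
    """
    diff = moving_n - fixed_n
    gr_f, gc_f = np.gradient(fixed_n)
    gr_m, gc_m = np.gradient(moving_n)
    gr = 0.5 * (gr_f + gr_m)
    gc = 0.5 * (gc_f + gc_m)
    denom = gr * gr + gc * gc + diff * diff
    with np.errstate(invalid="ignore"):
        scale = np.where(denom > 1e-9, -diff / np.maximum(denom, 1e-9), 0.0)
    return np.stack([scale * gr, scale * gc])


def _similarity(fixed_n: np.ndarray, moving_n: np.ndarray) -> float:
    """Negative mean squared difference of standardized images (higher = better)."""
    return float(-np.mean((fixed_n - moving_n) ** 2))


def _pyramid(img: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Coarse-to-fine Gaussian pyramid, factor 2 with anti-aliasing."""
    levels = [img]
    for _ in range(n_levels - 1):
        prev = levels[-1]
        shape = (max(4, int(np.ceil(prev.shape[0] / 2))), max(4, int(np.ceil(prev.shape[1] / 2))))
        levels.append(resize(prev, shape, order=1, anti_aliasing=True, mode="edge"))
    return levels[::-1]  # coarsest first


def register_pair(
    fixed: np.ndarray,
    moving: np.ndarray,
    params: RegistrationParams | None = None,
) -> DisplacementFieldPair:
    """Register ``moving`` to ``fixed``, returning mutually inverse fields.

    The optimization treats the two images symmetrically: each iteration
    warps the moving image forward and the fixed image backward and averages
    the opposed demons forces, so swapping the inputs swaps the roles of the
    two fields.  There is no randomness; identical inputs give bit-identical
    output.  Non-convergence is not an error: if the final similarity is
    worse than the unregistered starting point the identity transform is
    returned with a warning.
    """
    if params is None:
        params = RegistrationParams()
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if fixed.shape != moving.shape or fixed.ndim != 2:
        raise ValueError(f"images must share a 2-D shape, got {fixed.shape} vs {moving.shape}")
    if not (np.isfinite(fixed).all() and np.isfinite(moving).all()):
        raise ValueError("image intensities must be finite")

    scale = max(fixed.std(), moving.std(), 1e-12)
    eps = (0.05 * scale) ** 2  # variance floor: flat/air regions produce no force

    fix_pyr = _pyramid(fixed, params.n_levels)
    mov_pyr = _pyramid(moving, params.n_levels)

    v: np.ndarray | None = None
    for level, (fl, ml, iters) in enumerate(zip(fix_pyr, mov_pyr, params.iters_per_level)):
        shape = fl.shape
        if v is None:
            v = np.zeros((2, *shape))
        elif v.shape[1:] != shape:
            v = np.stack([
                resize(v[0], shape, order=1, mode="edge") * (shape[0] / v.shape[1]),
                resize(v[1], shape, order=1, mode="edge") * (shape[1] / v.shape[2]),
            ])
        fl_n = _standardize(fl, params.lncc_window_sigma, eps)
        ml_n = _standardize(ml, params.lncc_window_sigma, eps)
        border = np.zeros(shape, dtype=bool)
        b = min(_BORDER_PX, shape[0] // 4, shape[1] // 4)
        if b > 0:
            border[:b] = border[-b:] = True
            border[:, :b] = border[:, -b:] = True
        for _ in range(iters):
            fwd = field_exp(v, params.n_squaring_steps)
            inv = field_exp(-v, params.n_squaring_steps)
            mov_w = _standardize(warp(ml, fwd), params.lncc_window_sigma, eps)
            fix_w = _standardize(warp(fl, inv), params.lncc_window_sigma, eps)
            u_f = _demons_update(fl_n, mov_w)   # on fixed grid
            u_b = _demons_update(ml_n, fix_w)   # on moving grid
            upd = 0.5 * (u_f - u_b)
            upd[:, border] = 0.0
            upd[0] = gaussian_filter(upd[0], params.sigma_fluid, mode="nearest")
            upd[1] = gaussian_filter(upd[1], params.sigma_fluid, mode="nearest")
            v = v + params.step_scale * upd
            v[0] = gaussian_filter(v[0], params.sigma_diffusion, mode="nearest")
            v[1] = gaussian_filter(v[1], params.sigma_diffusion, mode="nearest")

    assert v is not None
    forward = field_exp(v, params.n_squaring_steps)
    inverse = field_exp(-v, params.n_squaring_steps)

    fix_n = fix_pyr[-1]
    eps_full = eps
    f_std = _standardize(fix_n, params.lncc_window_sigma, eps_full)
    sim0 = _similarity(f_std, _standardize(moving, params.lncc_window_sigma, eps_full))
    sim1 = _similarity(f_std, _standardize(warp(moving, forward), params.lncc_window_sigma, eps_full))
    if sim1 < sim0:
        logger.warning("registration did not improve similarity; returning identity transform")
        zero = np.zeros_like(forward)
        return DisplacementFieldPair(zero, zero.copy(), converged=False, final_similarity=sim0)

    pair = DisplacementFieldPair(forward, inverse, final_similarity=sim1)
    ic = inverse_consistency_error(pair)
    if ic > 10 * params.ic_tol:
        logger.warning("inverse-consistency residual %.3f px exceeds 10 x ic_tol", ic)
        pair.converged = False
    return pair
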