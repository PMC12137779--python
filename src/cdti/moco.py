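"""The two registration schedules that turn a raw series into motion-corrected maps' input.

``moco_naive`` registers every diffusion-weighted frame directly to the first
acquired low-b frame.  ``moco_avg`` proceeds in three stages: (1) register
the low-b frames to the first low-b frame and average them into a
high-SNR reference; (2) register every high-b frame to that reference and
average within each diffusion direction; (3) re-register each per-direction
high-b average to the reference.  The averaged reference tolerates the low
SNR of individual high-b frames, which is what makes the staged scheme the
more robust of the two.

Each frame is resampled exactly once, by the field that maps reference-grid
points into the moving frame, so averaging happens after a single
interpolation.  Frames whose registration fails the inverse-consistency
check are flagged (``MocoResult.flagged``) but never discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .io_formats import DiffusionScheme, ImageSeries
from .registration import (
    DisplacementFieldPair,
    RegistrationParams,
    register_pair,
    warp,
)

logger = logging.getLogger(__name__)

__all__ = ["MocoResult", "moco_naive", "moco_avg", "average_by_direction", "scheme_for"]


@dataclass
class MocoResult:
    """Output of one MOCO schedule on one slice series."""

    corrected_series: ImageSeries
    averaged_series: ImageSeries
    reference: np.ndarray
    fields: list[DisplacementFieldPair]
    strategy: str
    flagged: list[int] = dc_field(default_factory=list)
    stage3_fields: list[DisplacementFieldPair] | None = None


def average_by_direction(series: ImageSeries) -> ImageSeries:
    """Arithmetic mean over averages within each (b_value, direction) group.

    Output frames are ordered low shell first, then by direction index, with
    ``average_index`` reset to 0.
    """
    meta = series.frame_meta
    groups = sorted(
        {(float(r.b_value), int(r.direction_index)) for r in meta.itertuples()}
    )
    frames, rows = [], []
    for order, (b, d) in enumerate(groups):
        sel = (meta["b_value"].to_numpy() == b) & (meta["direction_index"].to_numpy() == d)
        frames.append(series.frames[sel].mean(axis=0))
        rows.append({"b_value": b, "direction_index": d, "average_index": 0,
                     "acquisition_order": order})
    return ImageSeries(np.stack(frames), series.pixel_spacing_mm,
                       pd.DataFrame(rows), series.slice_index)


def scheme_for(series: ImageSeries, directions: np.ndarray) -> DiffusionScheme:
    """Diffusion scheme matching a series' frame order, from a direction table."""
    directions = np.asarray(directions, float)
    idx = series.frame_meta["direction_index"].to_numpy(int)
    return DiffusionScheme(series.b_values, directions[idx])


def _register_to(
    reference: np.ndarray,
    series: ImageSeries,
    sel: np.ndarray,
    params: RegistrationParams,
    fields: dict[int, DisplacementFieldPair],
    flagged: list[int],
    corrected: np.ndarray,
) -> None:
    """Register selected frames to the reference, in acquisition order."""
    from .registration import inverse_consistency_error

    for i in np.flatnonzero(sel):
        pair = register_pair(reference, series.frames[i], params)
        fields[i] = pair
        corrected[i] = warp(series.frames[i], pair.forward)
        if inverse_consistency_error(pair) > 10 * params.ic_tol:
            flagged.append(int(i))
            logger.warning("frame %d: registration flagged (not discarded)", i)


def _check_first_frame_low_b(series: ImageSeries) -> None:
    first_b = float(series.frame_meta.loc[0, "b_value"])
    if first_b != series.low_b:
        raise ValueError(
            "protocol assumption violated: the first acquired frame must be a "
            f"low-b frame (b = {series.low_b:g}), got b = {first_b:g}"
        )


def moco_naive(series: ImageSeries, params: RegistrationParams | None = None) -> MocoResult:
    """Register every frame to the first acquired low-b frame, then average.

    The reference is the first acquired frame itself (which the protocol
    guarantees is low-b); all frames, low- and high-b alike, are registered
    to it in one pass.
    """
    if params is None:
        params = RegistrationParams()
    if not (series.b_values == series.low_b).any():
        raise ValueError("series contains no low-b frame")
    _check_first_frame_low_b(series)
    reference = series.frames[0].copy()
    corrected = np.empty_like(series.frames)
    fields: dict[int, DisplacementFieldPair] = {}
    flagged: list[int] = []
    _register_to(reference, series, np.ones(series.n_frames, bool), params,
                 fields, flagged, corrected)
    corrected_series = series.with_frames(corrected)
    return MocoResult(
        corrected_series=corrected_series,
        averaged_series=average_by_direction(corrected_series),
        reference=reference,
        fields=[fields[i] for i in range(series.n_frames)],
        strategy="naive",
        flagged=flagged,
    )


def moco_avg(series: ImageSeries, params: RegistrationParams | None = None) -> MocoResult:
    """Three-stage schedule with an averaged low-b reference.

    Stage 1 registers the low-b frames to the first of them and averages the
    results into the reference.  Stage 2 registers each high-b frame to the
    reference and averages within direction.  Stage 3 registers each
    per-direction high-b average to the reference once more.  The averaged
    output holds the stage-1-corrected low-b frames (one per direction — the
    protocol acquires a single average there) plus the stage-3 high-b
    averages.
    """
    if params is None:
        params = RegistrationParams()
    meta = series.frame_meta
    low_sel = (series.b_values == series.low_b)
    if not low_sel.any():
        raise ValueError("series contains no low-b frame")
    _check_first_frame_low_b(series)
    low_dirs = set(meta.loc[low_sel, "direction_index"].astype(int))
    high_sel = ~low_sel
    if high_sel.any():
        missing = sorted(set(meta.loc[high_sel, "direction_index"].astype(int)) - low_dirs)
        all_dirs = sorted(set(meta["direction_index"].astype(int)))
        absent = sorted(set(all_dirs) - low_dirs)
        if absent:
            raise ValueError(f"low-b frame missing for direction indices {absent}")
    dup = meta.loc[low_sel].groupby("direction_index").size()
    if (dup > 1).any():
        raise ValueError("expected exactly one low-b frame per direction")

    corrected = np.empty_like(series.frames)
    fields: dict[int, DisplacementFieldPair] = {}
    flagged: list[int] = []

    # stage 1: low-b frames to the first low-b frame
    first_low = int(np.flatnonzero(low_sel)[0])
    _register_to(series.frames[first_low], series, low_sel, params,
                 fields, flagged, corrected)
    reference = corrected[low_sel].mean(axis=0)

    # stage 2: individual high-b frames to the averaged reference
    _register_to(reference, series, high_sel, params, fields, flagged, corrected)
    corrected_series = series.with_frames(corrected)

    # per-direction high-b averages
    high_avg = average_by_direction(corrected_series.subset(high_sel))

    # stage 3: re-register each high-b average to the reference
    stage3: list[DisplacementFieldPair] = []
    avg_frames = high_avg.frames.copy()
    for i in range(high_avg.n_frames):
        pair = register_pair(reference, high_avg.frames[i], params)
        stage3.append(pair)
        avg_frames[i] = warp(high_avg.frames[i], pair.forward)

    # assemble averaged output: corrected low-b frames + stage-3 high-b averages
    low_idx = np.flatnonzero(low_sel)
    low_order = np.argsort(meta.loc[low_sel, "direction_index"].to_numpy(int), kind="stable")
    frames, rows = [], []
    order = 0
    for j in low_idx[low_order]:
        frames.append(corrected[j])
        rows.append({"b_value": series.low_b,
                     "direction_index": int(meta.loc[j, "direction_index"]),
                     "average_index": 0, "acquisition_order": order})
        order += 1
    for i in range(high_avg.n_frames):
        frames.append(avg_frames[i])
        rows.append({"b_value": float(high_avg.frame_meta.loc[i, "b_value"]),
                     "direction_index": int(high_avg.frame_meta.loc[i, "direction_index"]),
                     "average_index": 0, "acquisition_order": order})
        order += 1
    averaged = ImageSeries(np.stack(frames), series.pixel_spacing_mm,
                           pd.DataFrame(rows), series.slice_index)

    return MocoResult(
        corrected_series=corrected_series,
        averaged_series=averaged,
        reference=reference,
        fields=[fields[i] for i in range(series.n_frames)],
        strategy="avg",
        flagged=flagged,
        stage3_fields=stage3,
    )
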