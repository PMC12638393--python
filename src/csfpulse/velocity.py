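"""Velocity reconstruction from cine phase images.

Standard PC-MRI calibration maps a stored phase ``phi`` (radians, wrapped to
``[-pi, pi)``) to a signed through-plane velocity ``v = venc * phi / pi``
(cm/s). Two optional corrections follow:

* **Temporal unaliasing** — when the true speed exceeds venc, the stored
  phase wraps and the apparent velocity jumps by ``2*venc`` between frames.
  Per-voxel 1-D phase unwrapping along the cardiac dimension removes these
  jumps; among the resulting ``+/- 2*venc`` branches the one with the
  smallest absolute temporal mean is kept (CSF oscillatory flow is near
  zero-mean, which makes that branch the physical one).
* **Background (eddy-current) offset correction** — subtracts the static
  tissue velocity offset, by default a single scalar per series (the median
  over a static-tissue mask across all frames), so genuine pulsatility is
  not removed.

Both corrections are switchable off to mimic a minimal processing chain.
"""

from __future__ import annotations

import numpy as np

from .datatypes import CinePhaseSeries, VelocityField

__all__ = ["phase_to_velocity", "unalias_temporal", "background_correct"]


def phase_to_velocity(series: CinePhaseSeries) -> VelocityField:
    """Convert a cine phase series to a calibrated velocity field (cm/s)."""
    if series.venc_cms <= 0:
        raise ValueError("venc must be positive")
    v = series.venc_cms * series.phase / np.pi
    return VelocityField(
        velocity=v,
        venc_cms=series.venc_cms,
        pixel_spacing_mm=series.pixel_spacing_mm,
        period_s=series.period_s,
    )


def unalias_temporal(field: VelocityField, venc_cms: float | None = None) -> VelocityField:
    """Correct velocity aliasing by per-voxel temporal phase unwrapping.

    Frame-to-frame velocity jumps larger than venc are treated as phase
    wraps: ``2*venc`` multiples are added/subtracted to later samples
    (numpy's 1-D unwrap along the cardiac axis), then each voxel's branch is
    shifted by the multiple of ``2*venc`` that minimizes the absolute
    temporal mean. A no-op (returns an equal field) when no jump exceeds
    venc. Idempotent.
    """
    venc = field.venc_cms if venc_cms is None else float(venc_cms)
    if venc <= 0:
        raise ValueError("venc must be positive")
    v = field.velocity
    unwrapped = np.unwrap(v, axis=-1, period=2.0 * venc)
    # branch selection: minimal |temporal mean| (ties resolved toward zero
    # offset by round-half-to-even on the branch index)
    offset = 2.0 * venc * np.round(unwrapped.mean(axis=-1, keepdims=True) / (2.0 * venc))
    corrected = unwrapped - offset
    changed = not np.allclose(corrected, v)
    return VelocityField(
        velocity=corrected,
        venc_cms=field.venc_cms,
        pixel_spacing_mm=field.pixel_spacing_mm,
        period_s=field.period_s,
        aliasing_corrected=field.aliasing_corrected or changed,
        background_corrected=field.background_corrected,
    )


def background_correct(
    field: VelocityField,
    static_mask: np.ndarray,
    mode: str = "scalar",
) -> VelocityField:
    """Subtract the static-tissue velocity offset.

    Parameters
    ----------
    static_mask
        Boolean raster of voxels assumed static (disjoint from the lumen).
    mode
        ``"scalar"`` (default): one offset for the whole series, the median
        velocity over the static mask and all frames — models a constant
        eddy-current offset without touching pulsatility. ``"per_frame"``:
        one median offset per cardiac phase.
    """
    static_mask = np.asarray(static_mask, dtype=bool)
    if static_mask.shape != field.velocity.shape[:2]:
        raise ValueError("static mask shape does not match the image grid")
    if not static_mask.any():
        raise ValueError("static mask is empty")
    if mode == "scalar":
        offset = np.median(field.velocity[static_mask, :])
        corrected = field.velocity - offset
    elif mode == "per_frame":
        offset = np.median(field.velocity[static_mask, :], axis=0)
        corrected = field.velocity - offset[None, None, :]
    else:
        raise ValueError("mode must be 'scalar' or 'per_frame'")
    return VelocityField(
        velocity=corrected,
        venc_cms=field.venc_cms,
        pixel_spacing_mm=field.pixel_spacing_mm,
        period_s=field.period_s,
        aliasing_corrected=field.aliasing_corrected,
        background_corrected=True,
    )
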