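"""Semi-automatic ROI delineation driven by CSF pulsatility.

The lumen of a CSF pathway stands out in a cine velocity series by its
peak-to-peak velocity amplitude over the cardiac cycle. Segmentation here is
seeded region growing on that pulsatility map: starting from a user-supplied
pixel, the 4-connected region of voxels whose amplitude is at least a fixed
fraction of the seed's amplitude is grown. One tunable parameter
(``threshold_frac``, default 0.2) keeps the procedure reproducible; a manual
polygon ROI (even-odd rule on voxel centers) is provided for structures
delineated by hand, such as the narrowest aqueduct cross-section.

4-connectivity (not 8) is used so the region cannot leak diagonally through
thin septa between adjacent CSF spaces. Coordinates are (row, col), 0-based,
with voxel centers at integer coordinates.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .datatypes import PulsatilityMap, ROIMask, VelocityField

__all__ = ["pulsatility_map", "segment_roi", "manual_roi"]

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def pulsatility_map(field: VelocityField) -> PulsatilityMap:
    """Peak-to-peak velocity amplitude per voxel over the cardiac cycle."""
    if field.n_phases < 2:
        raise ValueError("need at least 2 cardiac phases")
    amp = field.velocity.max(axis=-1) - field.velocity.min(axis=-1)
    return PulsatilityMap(amplitude=amp)


def segment_roi(
    pmap: PulsatilityMap,
    seed: tuple[int, int],
    threshold_frac: float = 0.2,
    site: str = "aqu",
    pixel_area_mm2: float = 1.0,
) -> ROIMask:
    """Grow the ROI from a seed pixel on the pulsatility map.

    The mask is exactly the 4-connected component, containing the seed, of
    voxels with ``amplitude >= threshold_frac * amplitude(seed)``. Monotone
    non-increasing in ``threshold_frac``, and always contains the seed.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must lie in (0, 1)")
    amp = pmap.amplitude
    r, c = int(seed[0]), int(seed[1])
    if not (0 <= r < amp.shape[0] and 0 <= c < amp.shape[1]):
        raise ValueError("seed outside image bounds")
    if amp[r, c] <= 0:
        raise ValueError("seed not pulsatile")
    above = amp >= threshold_frac * amp[r, c]
    labels, _ = ndimage.label(above, structure=_FOUR_CONNECTED)
    mask = labels == labels[r, c]
    return ROIMask(mask=mask, site=site, pixel_area_mm2=pixel_area_mm2)


def manual_roi(
    polygon: list[tuple[float, float]],
    grid_shape: tuple[int, int],
    pixel_area_mm2: float = 1.0,
    site: str = "aqu",
) -> ROIMask:
    """Rasterize a hand-drawn polygon into an ROI mask.

    A voxel belongs to the ROI iff its center (integer (row, col) coordinate)
    lies inside the polygon under the even-odd fill rule. Degenerate polygons
    (fewer than 3 vertices, zero area, or enclosing no voxel center) raise.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise ValueError("polygon needs at least 3 (row, col) vertices")
    # shoelace area
    x, y = poly[:, 1], poly[:, 0]
    area2 = np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area2 == 0:
        raise ValueError("degenerate polygon (zero area)")
    rr, cc = np.mgrid[0 : grid_shape[0], 0 : grid_shape[1]]
    inside = _even_odd_inside(poly, rr.ravel().astype(float), cc.ravel().astype(float))
    inside = inside.reshape(grid_shape)
    if not inside.any():
        raise ValueError("polygon encloses no voxel center")
    return ROIMask(mask=inside, site=site, pixel_area_mm2=pixel_area_mm2)


def _even_odd_inside(poly: np.ndarray, pr: np.ndarray, pc: np.ndarray) -> np.ndarray:
    """Vectorized even-odd (ray-casting) point-in-polygon test.

    Casts a ray in the +col direction from each point and counts edge
    crossings; an odd count means inside. Half-open vertex handling
    (``r1 <= p < r2``) counts each vertex crossing exactly once.
    """
    inside = np.zeros(pr.shape, dtype=bool)
    n = poly.shape[0]
    for i in range(n):
        r1, c1 = poly[i]
        r2, c2 = poly[(i + 1) % n]
        if r1 == r2:
            continue  # horizontal edge never crosses a horizontal ray
        spans = (pr >= min(r1, r2)) & (pr < max(r1, r2))
        # col coordinate where the edge crosses the point's row
        c_cross = c1 + (pr - r1) * (c2 - c1) / (r2 - r1)
        inside ^= spans & (c_cross > pc)
    return inside
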