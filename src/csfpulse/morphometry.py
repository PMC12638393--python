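"""Morphological indices: Evans index and narrowest aqueduct cross-section.

The Evans index (maximum frontal-horn width over maximum inner biparietal
diameter, on an axial slice) is a standard ventriculomegaly marker with
~0.3 as the conventional abnormality threshold. It consumes two scalar
caliper measurements, as a manual reading would — ventricle segmentation is
deliberately out of scope. The aqueduct cross-sectional area is the area of
a (typically hand-drawn) ROI mask on the axial slice where the aqueduct is
narrowest.
"""

from __future__ import annotations

from .datatypes import ROIMask

__all__ = ["evans_index", "mask_area", "narrowest_slice"]


def evans_index(frontal_horn_width_mm: float, biparietal_diameter_mm: float) -> float:
    """Ratio of maximum frontal-horn width to maximum biparietal diameter."""
    if frontal_horn_width_mm <= 0 or biparietal_diameter_mm <= 0:
        raise ValueError("both measurements must be positive")
    if frontal_horn_width_mm >= biparietal_diameter_mm:
        raise ValueError(
            "frontal-horn width must be smaller than the biparietal diameter"
        )
    return frontal_horn_width_mm / biparietal_diameter_mm


def mask_area(roi: ROIMask) -> float:
    """Area of an ROI mask in mm^2 (voxel count times pixel area)."""
    if not roi.mask.any():
        raise ValueError("empty mask")
    return roi.area_mm2


def narrowest_slice(areas: list[tuple[int, float]]) -> tuple[int, float]:
    """Pick the slice with minimal cross-sectional area.

    ``areas`` is a list of ``(slice_index, area_mm2)``. Ties resolve to the
    smallest slice index.
    """
    if not areas:
        raise ValueError("empty slice list")
    return min(areas, key=lambda item: (item[1], item[0]))
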