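"""Shared data containers for the cine phase-contrast CSF flow pipeline.

Conventions used throughout the package:

* Rasters are ``(row, col)`` or ``(row, col, cardiac_phase)`` numpy arrays,
  0-based, with voxel centers at integer coordinates.
* Phase images are in radians, wrapped to ``[-pi, pi)``; a phase of ``pi``
  maps to the velocity-encoding limit ``venc`` (cm/s).
* Velocities are signed cm/s (positive = through-plane reference direction,
  cranio-caudal in sagittal-axis planes); in-plane areas are mm^2; flow rates
  are uL/s; displaced volumes are uL per cardiac cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical measurement-site keys: aqueduct of Sylvius, prepontine cistern,
#: foramen magnum, cerebellar tonsils / neuraxis, and C2-C3 subarachnoid space.
SITES = ("aqu", "ppc", "fm", "nevrax", "c2c3")

#: Accepted aliases for site keys (``tonsils`` is the anatomical synonym for
#: the neuraxis/cerebellar-tonsil level).
SITE_ALIASES = {"tonsils": "nevrax", "c2-c3": "c2c3", "c2_c3": "c2c3"}


def canonical_site(site: str) -> str:
    """Normalize a measurement-site name to its canonical key."""
    key = site.strip().lower()
    key = SITE_ALIASES.get(key, key)
    if key not in SITES:
        raise ValueError(f"unknown measurement site {site!r}; expected one of {SITES}")
    return key


def wrap_phase(phi: np.ndarray | float) -> np.ndarray:
    """Wrap phase values (radians) into ``[-pi, pi)``."""
    return np.mod(np.asarray(phi, dtype=float) + np.pi, 2.0 * np.pi) - np.pi


@dataclass
class CinePhaseSeries:
    """Cardiac-gated phase-contrast series for a single imaging plane.

    Parameters
    ----------
    phase
        ``(row, col, cardiac_phase)`` phase raster in radians, wrapped to
        ``[-pi, pi)``.
    magnitude
        Same-shape magnitude raster, arbitrary units.
    venc_cms
        Velocity-encoding limit in cm/s: the velocity mapped to a phase of
        ``+/-pi``. Typical protocol values are 10 cm/s for the aqueduct plane
        and 5 cm/s elsewhere; any positive value is accepted.
    pixel_spacing_mm
        In-plane ``(row, col)`` spacing in mm.
    period_s
        Duration of the cardiac cycle in seconds.
    """

    phase: np.ndarray
    magnitude: np.ndarray
    venc_cms: float
    pixel_spacing_mm: tuple[float, float]
    period_s: float

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.phase.ndim != 3:
            raise ValueError("phase must be a (row, col, cardiac_phase) raster")
        if self.phase.shape != self.magnitude.shape:
            raise ValueError("magnitude/phase shape mismatch")
        if self.n_phases < 8:
            raise ValueError("need at least 8 cardiac phases")
        if self.venc_cms <= 0:
            raise ValueError("venc must be positive")
        if self.period_s <= 0:
            raise ValueError("cardiac period must be positive")
        if np.any(self.phase < -np.pi) or np.any(self.phase >= np.pi):
            raise ValueError("phase values must lie in [-pi, pi)")

    @property
    def n_phases(self) -> int:
        return self.phase.shape[2]

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.pixel_spacing_mm[0] * self.pixel_spacing_mm[1])


@dataclass
class VelocityField:
    """Voxel-wise signed velocity time series (cm/s) over one cardiac cycle."""

    velocity: np.ndarray  # (row, col, cardiac_phase), cm/s
    venc_cms: float
    pixel_spacing_mm: tuple[float, float]
    period_s: float
    aliasing_corrected: bool = False
    background_corrected: bool = False

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.velocity.ndim != 3:
            raise ValueError("velocity must be a (row, col, cardiac_phase) raster")

    @property
    def n_phases(self) -> int:
        return self.velocity.shape[2]

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.pixel_spacing_mm[0] * self.pixel_spacing_mm[1])


@dataclass
class PulsatilityMap:
    """Per-voxel peak-to-peak velocity amplitude (cm/s) over the cycle."""

    amplitude: np.ndarray  # (row, col), >= 0

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.ndim != 2:
            raise ValueError("amplitude must be a 2-D raster")
        if np.any(self.amplitude < 0):
            raise ValueError("pulsatility amplitude must be non-negative")


@dataclass
class ROIMask:
    """Binary region of interest in one imaging plane."""

    mask: np.ndarray  # (row, col) bool
    site: str
    pixel_area_mm2: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D raster")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")
        self.site = canonical_site(self.site)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def area_mm2(self) -> float:
        return self.n_voxels * self.pixel_area_mm2


@dataclass
class FlowCurve:
    """Flow rate through an ROI at each cardiac phase.

    ``q`` is in uL/s with one sample per cardiac phase (uniformly spaced over
    ``period_s``; sample ``k`` is at time ``k * period_s / len(q)``).
    """

    q: np.ndarray
    period_s: float
    site: str

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 1 or self.q.size < 2:
            raise ValueError("flow curve must be a 1-D series of >= 2 samples")
        if not np.all(np.isfinite(self.q)):
            raise ValueError("flow curve contains non-finite values")
        self.site = canonical_site(self.site)

    @property
    def n_phases(self) -> int:
        return self.q.size


@dataclass
class StrokeVolumeResult:
    """Stroke volume and net displaced volume at a named anatomical site.

    The stroke volume is the mean of the two directional displaced volumes,
    ``SV = (V+ + V-) / 2`` (uL per cardiac cycle); the net volume is their
    signed difference ``V+ - V-`` (bulk flow over the cycle).
    """

    sv_ul_per_cc: float
    net_volume_ul: float
    v_plus_ul: float
    v_minus_ul: float
    site: str
    processing: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.site = canonical_site(self.site)
        if self.sv_ul_per_cc < 0:
            raise ValueError("stroke volume cannot be negative")

    def as_dict(self) -> dict:
        return {
            "site": self.site,
            "sv_ul_per_cc": self.sv_ul_per_cc,
            "net_volume_ul": self.net_volume_ul,
            "v_plus_ul": self.v_plus_ul,
            "v_minus_ul": self.v_minus_ul,
            "processing": dict(self.processing),
        }
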