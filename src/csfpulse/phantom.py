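"""Cine phase-contrast flow phantoms with analytically known stroke volume.

The phantom emulates a cardiac-gated PC-MRI acquisition of pulsatile laminar
flow through a small lumen (circular or annular cross-section) surrounded by
static tissue: the mean-lumen velocity follows a finite Fourier waveform, the
in-plane profile is either plug or Poiseuille (parabolic), and the stored
phase image is ``pi * v / venc`` plus an optional constant background offset
and i.i.d. Gaussian phase noise, wrapped to ``[-pi, pi)`` exactly as a
scanner would store it. The analytic flow curve and stroke volume are
returned alongside, so every downstream stage can be validated against a
closed-form truth.

Not modelled (out of scope by design): Womersley frequency-dependent
profiles, k-space/acquisition physics, gating jitter and heart-rate
variability, and through-plane angulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import CinePhaseSeries, wrap_phase

__all__ = [
    "WaveformTerm",
    "PhantomSpec",
    "PhantomTruth",
    "generate_waveform",
    "generate_cine_series",
    "analytic_stroke_volume",
]


@dataclass(frozen=True)
class WaveformTerm:
    """One harmonic of the mean-lumen velocity waveform.

    Contributes ``amplitude_cms * sin(2*pi*harmonic*t/T + phase_rad)``.
    """

    amplitude_cms: float
    harmonic: int = 1
    phase_rad: float = 0.0


@dataclass
class PhantomSpec:
    """Specification of a pulsatile-flow phase-contrast phantom.

    Parameters
    ----------
    geometry
        ``"circle"`` or ``"annulus"``.
    center_mm
        Lumen center ``(row, col)`` in mm.
    radius_mm
        Outer radius in mm.
    inner_radius_mm
        Inner radius in mm (annulus only; must be < ``radius_mm``).
    profile
        ``"plug"`` (uniform) or ``"poiseuille"`` (parabolic; lumen mean equals
        the waveform value, so the centerline velocity is twice it; for the
        annulus the plug approximation of the parabolic profile uses the
        normalized distance between the two walls).
    waveform
        Harmonics of the mean-lumen velocity v(t) over one period (cm/s).
    period_s, n_phases
        Cardiac period and number of uniformly spaced frames per cycle.
    venc_cms
        Velocity encoding; lumen velocities beyond it alias (wrap) in the
        stored phase image.
    noise_sd_rad
        SD of i.i.d. Gaussian phase noise added everywhere (lumen and static
        tissue alike).
    background_offset_rad
        Constant phase offset added everywhere (models eddy-current offset).
    """

    geometry: str = "circle"
    center_mm: tuple[float, float] | None = None
    radius_mm: float = 1.5
    inner_radius_mm: float = 0.0
    profile: str = "plug"
    waveform: tuple[WaveformTerm, ...] = (WaveformTerm(1.0, 1, 0.0),)
    period_s: float = 1.0
    n_phases: int = 32
    venc_cms: float = 10.0
    pixel_spacing_mm: tuple[float, float] = (0.3, 0.3)
    grid_shape: tuple[int, int] = (32, 32)
    noise_sd_rad: float = 0.0
    background_offset_rad: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("circle", "annulus"):
            raise ValueError("geometry must be 'circle' or 'annulus'")
        if self.profile not in ("plug", "poiseuille"):
            raise ValueError("profile must be 'plug' or 'poiseuille'")
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")
        if self.geometry == "annulus":
            if not 0 < self.inner_radius_mm < self.radius_mm:
                raise ValueError("annulus requires 0 < inner radius < outer radius")
        if self.n_phases < 8:
            raise ValueError("need at least 8 cardiac phases")
        if self.venc_cms <= 0 or self.period_s <= 0:
            raise ValueError("venc and period must be positive")
        self.waveform = tuple(
            t if isinstance(t, WaveformTerm) else WaveformTerm(*t) for t in self.waveform
        )
        if len(self.waveform) == 0:
            raise ValueError("waveform must contain at least one harmonic term")
        if self.center_mm is None:
            # default: grid center
            self.center_mm = (
                (self.grid_shape[0] - 1) / 2.0 * self.pixel_spacing_mm[0],
                (self.grid_shape[1] - 1) / 2.0 * self.pixel_spacing_mm[1],
            )

    # -- analytic pieces -------------------------------------------------

    def lumen_area_mm2(self) -> float:
        """Analytic lumen cross-sectional area in mm^2."""
        area = np.pi * self.radius_mm**2
        if self.geometry == "annulus":
            area -= np.pi * self.inner_radius_mm**2
        return float(area)

    def mean_velocity(self, t: np.ndarray | float) -> np.ndarray:
        """Mean-lumen velocity v(t) in cm/s at time(s) ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        v = np.zeros_like(t)
        for term in self.waveform:
            v = v + term.amplitude_cms * np.sin(
                2.0 * np.pi * term.harmonic * t / self.period_s + term.phase_rad
            )
        return v

    def flow_rate(self, t: np.ndarray | float) -> np.ndarray:
        """Analytic flow rate Q(t) in uL/s (area mm^2 x velocity cm/s x 10)."""
        return self.lumen_area_mm2() * self.mean_velocity(t) * 10.0


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a generated phantom series."""

    flow_curve_true: np.ndarray  # uL/s at each stored frame
    sv_true_ul: float
    net_volume_true_ul: float
    lumen_mask_true: np.ndarray  # (row, col) bool
    peak_velocity_cms: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.flow_curve_true = np.asarray(self.flow_curve_true, dtype=float)
        self.lumen_mask_true = np.asarray(self.lumen_mask_true, dtype=bool)
        if self.sv_true_ul < 0:
            raise ValueError("true stroke volume cannot be negative")
        if not self.lumen_mask_true.any():
            raise ValueError("true lumen mask is empty")


def generate_waveform(spec: PhantomSpec) -> np.ndarray:
    """Sample the mean-lumen velocity waveform at the phantom's frame times.

    Returns v(t_k) in cm/s at ``t_k = k * T / n_phases`` for
    ``k = 0 .. n_phases - 1``.
    """
    t = np.arange(spec.n_phases) * spec.period_s / spec.n_phases
    return spec.mean_velocity(t)


def analytic_stroke_volume(spec: PhantomSpec, n_samples: int = 4096) -> float:
    """Stroke volume (uL per cycle) of the phantom's analytic flow curve.

    Computed as ``(V+ + V-) / 2`` where ``V+`` and ``V-`` are the forward and
    backward displaced volumes, by high-resolution trapezoidal quadrature of
    the closed-form Q(t) over one period (the grid is fine enough that
    zero-crossing placement error is negligible).
    """
    if n_samples < 4096:
        raise ValueError("use at least 4096 quadrature samples")
    t = np.linspace(0.0, spec.period_s, n_samples + 1)
    q = spec.flow_rate(t)
    v_plus = np.trapezoid(np.clip(q, 0.0, None), t)
    v_minus = np.trapezoid(np.clip(-q, 0.0, None), t)
    return float(0.5 * (v_plus + v_minus))


def _radius_maps(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel-center distance from the lumen axis, and the lumen mask.

    A voxel belongs to the lumen iff its *center* lies inside the geometry.
    """
    rows = np.arange(spec.grid_shape[0])[:, None] * spec.pixel_spacing_mm[0]
    cols = np.arange(spec.grid_shape[1])[None, :] * spec.pixel_spacing_mm[1]
    r = np.hypot(rows - spec.center_mm[0], cols - spec.center_mm[1])
    mask = r < spec.radius_mm
    if spec.geometry == "annulus":
        mask &= r >= spec.inner_radius_mm
    return r, mask


def _profile_weights(spec: PhantomSpec, r: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Spatial velocity profile normalized so the analytic lumen mean is 1."""
    w = np.zeros(spec.grid_shape, dtype=float)
    if spec.profile == "plug":
        w[mask] = 1.0
        return w
    # Parabolic (Poiseuille-type) profile, normalized so the area-weighted
    # lumen mean equals 1: circle v = 2*(1 - (r/R)^2); annulus v =
    # 1.5*(1 - rho^2) with rho the normalized gap coordinate between the
    # walls (area-weighted mean of (1 - rho^2) over the annulus is 2/3).
    if spec.geometry == "circle":
        rho2 = (r / spec.radius_mm) ** 2
        factor = 2.0
    else:
        mid = 0.5 * (spec.inner_radius_mm + spec.radius_mm)
        half_gap = 0.5 * (spec.radius_mm - spec.inner_radius_mm)
        rho2 = ((r - mid) / half_gap) ** 2
        factor = 1.5
    w[mask] = factor * (1.0 - rho2[mask])
    return w


def generate_cine_series(spec: PhantomSpec) -> tuple[CinePhaseSeries, PhantomTruth]:
    """Simulate the stored magnitude/phase series and its analytic truth.

    The stored phase at frame ``k`` is
    ``wrap(pi * v(x, k) / venc + background_offset + noise)`` with
    ``v(x, k)`` the spatial profile scaled by the mean-lumen waveform inside
    the lumen and zero in static tissue. Magnitude is a simple two-level
    image (bright fluid, darker tissue) — sufficient for mask/overlay use.
    """
    r, mask = _radius_maps(spec)
    if not mask.any():
        raise ValueError("grid too small (or spacing too coarse) to contain the lumen")
    # require the lumen to fit fully inside the grid
    extent_r = (spec.grid_shape[0] - 1) * spec.pixel_spacing_mm[0]
    extent_c = (spec.grid_shape[1] - 1) * spec.pixel_spacing_mm[1]
    if (
        spec.center_mm[0] - spec.radius_mm < 0
        or spec.center_mm[1] - spec.radius_mm < 0
        or spec.center_mm[0] + spec.radius_mm > extent_r
        or spec.center_mm[1] + spec.radius_mm > extent_c
    ):
        raise ValueError("lumen geometry extends beyond the image grid")

    vbar = generate_waveform(spec)  # (n_phases,) cm/s
    weights = _profile_weights(spec, r, mask)  # (row, col)
    velocity = weights[:, :, None] * vbar[None, None, :]  # cm/s

    rng = np.random.default_rng(spec.seed)
    phase = np.pi * velocity / spec.venc_cms + spec.background_offset_rad
    if spec.noise_sd_rad > 0:
        phase = phase + rng.normal(0.0, spec.noise_sd_rad, size=phase.shape)
    phase = wrap_phase(phase)

    magnitude = np.where(mask, 1.0, 0.35)[:, :, None] * np.ones_like(phase)

    series = CinePhaseSeries(
        phase=phase,
        magnitude=magnitude,
        venc_cms=spec.venc_cms,
        pixel_spacing_mm=spec.pixel_spacing_mm,
        period_s=spec.period_s,
    )

    t = np.arange(spec.n_phases) * spec.period_s / spec.n_phases
    q_true = spec.flow_rate(t)
    sv = analytic_stroke_volume(spec)
    # net volume: plain integral of Q over the period (high-res quadrature)
    tt = np.linspace(0.0, spec.period_s, 4097)
    net = float(np.trapezoid(spec.flow_rate(tt), tt))
    truth = PhantomTruth(
        flow_curve_true=q_true,
        sv_true_ul=sv,
        net_volume_true_ul=net,
        lumen_mask_true=mask,
        peak_velocity_cms=float(np.max(np.abs(velocity))),
        meta={
            "lumen_area_mm2": spec.lumen_area_mm2(),
            "rasterized_area_mm2": float(mask.sum() * spec.pixel_spacing_mm[0] * spec.pixel_spacing_mm[1]),
            "profile": spec.profile,
            "geometry": spec.geometry,
        },
    )
    return series, truth
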