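"""End-to-end study replica: simulate, quantify, assemble, compare, report.

Binds the stages into one reproducible run: per-site flow phantoms are
simulated and pushed through the full quantification chain as an imaging
quality check, a synthetic cohort is drawn from the configured group
distributions, the group comparison and the stroke-volume dichotomization
analysis are run, and everything — per-patient table, comparison table,
threshold report, phantom QC and a provenance log of every stage parameter —
is written to the output directory. Deterministic given the config seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortSpec, generate_cohort
from .datatypes import SITES, CinePhaseSeries
from .flow import QuantifyConfig, quantify_site
from .io import SIDECAR_KEYS, read_series, write_series, write_truth
from .phantom import PhantomSpec, WaveformTerm, generate_cine_series
from .stats import (
    DEFAULT_THRESHOLD_RULES,
    compare_cohort,
    threshold_exclusivity,
)

__all__ = ["PipelineConfig", "validate_inputs", "run_study_replica", "site_phantom_spec"]

#: Protocol venc per measurement plane (cm/s): 10 at the aqueduct, 5 elsewhere.
DEFAULT_VENC = {"aqu": 10.0, "ppc": 5.0, "fm": 5.0, "nevrax": 5.0, "c2c3": 5.0}

# Representative lumen geometry per site for the phantom QC stage: a small
# circular aqueduct; larger circular cisternal lumens; an annular cervical
# subarachnoid space. Radii in mm.
_SITE_GEOMETRY = {
    "aqu": dict(geometry="circle", radius_mm=1.5, pixel_spacing_mm=(0.3, 0.3), grid_shape=(32, 32)),
    "ppc": dict(geometry="circle", radius_mm=4.0, pixel_spacing_mm=(0.6, 0.6), grid_shape=(32, 32)),
    "fm": dict(geometry="circle", radius_mm=5.0, pixel_spacing_mm=(0.6, 0.6), grid_shape=(40, 40)),
    "nevrax": dict(geometry="circle", radius_mm=4.0, pixel_spacing_mm=(0.6, 0.6), grid_shape=(32, 32)),
    "c2c3": dict(
        geometry="annulus", radius_mm=7.0, inner_radius_mm=5.0,
        pixel_spacing_mm=(0.6, 0.6), grid_shape=(48, 48),
    ),
}


@dataclass
class PipelineConfig:
    """Configuration of the full study replica."""

    venc_per_site: dict = field(default_factory=lambda: dict(DEFAULT_VENC))
    n_phases: int = 32
    threshold_frac: float = 0.2
    background_mode: str | None = "scalar"
    unalias: bool = True
    t_variant: str = "welch"
    alpha: float = 0.05
    phantom_noise_sd_rad: float = 0.0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    seed: int = 0
    outdir: str | Path = "csfpulse_out"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        for site, venc in self.venc_per_site.items():
            if venc <= 0:
                raise ValueError(f"venc for {site} must be positive")


def site_phantom_spec(
    site: str,
    sv_target_ul: float,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> PhantomSpec:
    """Phantom spec for one site whose analytic SV equals ``sv_target_ul``.

    SV is linear in the waveform amplitude: for a single-harmonic waveform
    ``SV = A_lumen * v_amp * T / pi`` (uL with area mm^2, velocity mm/s), so
    the amplitude is solved directly from the target.
    """
    cfg = config or PipelineConfig()
    geom = _SITE_GEOMETRY[site]
    base = PhantomSpec(
        **geom,
        profile="poiseuille",
        waveform=(WaveformTerm(1.0, 1, 0.0),),
        period_s=1.0,
        n_phases=cfg.n_phases,
        venc_cms=cfg.venc_per_site[site],
        noise_sd_rad=cfg.phantom_noise_sd_rad,
        seed=cfg.seed if seed is None else seed,
    )
    sv_unit = base.lumen_area_mm2() * 10.0 * base.period_s / np.pi  # SV at 1 cm/s
    amp = sv_target_ul / sv_unit
    return PhantomSpec(
        **geom,
        profile="poiseuille",
        waveform=(WaveformTerm(float(amp), 1, 0.0),),
        period_s=base.period_s,
        n_phases=base.n_phases,
        venc_cms=base.venc_cms,
        noise_sd_rad=base.noise_sd_rad,
        seed=base.seed,
    )


def validate_inputs(
    phase_path: str | Path,
    magnitude_path: str | Path,
    sidecar_path: str | Path,
) -> dict:
    """Check a series on disk and return its normalized metadata.

    Verifies the files exist, the sidecar carries every required key, the
    magnitude and phase rasters agree in shape, and phase values lie in
    ``[-pi, pi)`` (the CinePhaseSeries constructor enforces the latter two).
    """
    for p in (phase_path, magnitude_path, sidecar_path):
        if not Path(p).exists():
            raise FileNotFoundError(str(p))
    sidecar = json.loads(Path(sidecar_path).read_text())
    missing = [k for k in SIDECAR_KEYS if k not in sidecar]
    if missing:
        raise ValueError(f"sidecar missing required keys: {missing}")
    series = read_series(phase_path, magnitude_path, sidecar_path)
    return {
        "venc_cms": series.venc_cms,
        "period_s": series.period_s,
        "pixel_spacing_mm": list(series.pixel_spacing_mm),
        "n_phases": series.n_phases,
        "grid_shape": list(series.phase.shape[:2]),
    }


def _phantom_qc(config: PipelineConfig, outdir: Path) -> list[dict]:
    """Simulate and re-quantify one phantom per site; record recovery."""
    qc = []
    for site in SITES:
        # target the mid-cohort SV for the site (mean of the two group means)
        params = config.cohort.site_params[site]
        target = 0.5 * (params["relieved"].mean_ul + params["not_relieved"].mean_ul)
        spec = site_phantom_spec(site, target, config)
        series, truth = generate_cine_series(spec)
        stem = outdir / "phantoms" / site
        write_series(series, stem)
        write_truth(truth, stem.with_name(site + "_truth.json"))
        seed_pixel = tuple(np.argwhere(truth.lumen_mask_true)[0])
        # seed at the lumen centroid (inside for circle and annulus alike)
        idx = np.argwhere(truth.lumen_mask_true)
        centroid = idx.mean(axis=0)
        d2 = ((idx - centroid) ** 2).sum(axis=1)
        if spec.geometry == "annulus":
            seed_pixel = tuple(idx[np.argmin(np.abs(np.sqrt(d2) - 0.5 * (spec.inner_radius_mm + spec.radius_mm) / spec.pixel_spacing_mm[0]))])
        else:
            seed_pixel = tuple(idx[np.argmin(d2)])
        result = quantify_site(
            series,
            seed_pixel,
            site,
            QuantifyConfig(
                threshold_frac=config.threshold_frac,
                unalias=config.unalias,
                background_mode=config.background_mode,
                n_phases_out=config.n_phases,
            ),
        )
        rel_err = abs(result.sv_ul_per_cc - truth.sv_true_ul) / truth.sv_true_ul
        qc.append(
            {
                "site": site,
                "sv_true_ul": truth.sv_true_ul,
                "sv_measured_ul": result.sv_ul_per_cc,
                "relative_error": rel_err,
                "peak_velocity_cms": truth.peak_velocity_cms,
                "venc_cms": spec.venc_cms,
                "processing": result.processing,
            }
        )
    return qc


def run_study_replica(config: PipelineConfig) -> dict:
    """Run the full replica; returns the report bundle (also written to disk).

    Outputs in ``config.outdir``: ``cohort.csv`` (per-patient table),
    ``comparison.csv`` (per-variable group comparison with significance
    stars), ``thresholds.json`` (dichotomization report),
    ``phantom_qc.json`` (per-site simulate-and-requantify check) and
    ``provenance.json`` (every stage parameter and seed).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    qc = _phantom_qc(config, outdir)

    table = generate_cohort(config.cohort)
    table.to_csv(outdir / "cohort.csv", index=False, float_format="%.6g")

    comparisons = compare_cohort(
        table, alpha=config.alpha, t_variant=config.t_variant
    )
    comp_df = pd.DataFrame([c.as_dict() for c in comparisons])
    comp_df["star"] = np.where(comp_df["significant"], "*", "")
    comp_df.to_csv(outdir / "comparison.csv", index=False, float_format="%.6g")

    thresholds = threshold_exclusivity(table, DEFAULT_THRESHOLD_RULES)
    (outdir / "thresholds.json").write_text(json.dumps(thresholds, indent=2))
    (outdir / "phantom_qc.json").write_text(json.dumps(qc, indent=2))

    provenance = {
        "seed": config.seed,
        "cohort_seed": config.cohort.seed,
        "n_relieved": config.cohort.n_relieved,
        "n_not_relieved": config.cohort.n_not_relieved,
        "venc_per_site": config.venc_per_site,
        "n_phases": config.n_phases,
        "threshold_frac": config.threshold_frac,
        "background_mode": config.background_mode,
        "unalias": config.unalias,
        "t_variant": config.t_variant,
        "alpha": config.alpha,
        "phantom_noise_sd_rad": config.phantom_noise_sd_rad,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))

    return {
        "cohort": table,
        "comparisons": comparisons,
        "thresholds": thresholds,
        "phantom_qc": qc,
        "provenance": provenance,
        "outdir": outdir,
    }
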