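"""File I/O: 4D NIfTI cine series with JSON sidecar, DICOM import, PNG masks.

A phantom or acquired series is stored as two 4-D NIfTI files of shape
``(row, col, 1, cardiac_phase)`` — magnitude (arbitrary units) and phase
(radians, float) — plus a JSON sidecar holding the acquisition metadata the
images cannot carry: ``venc_cms``, ``period_s``, ``pixel_spacing_mm`` and
``n_phases``. Ground truth and ROI metadata are plain JSON; masks are 0/255
grayscale PNG; cohorts are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .datatypes import CinePhaseSeries, ROIMask
from .phantom import PhantomTruth

__all__ = [
    "write_series",
    "read_series",
    "write_truth",
    "read_truth",
    "write_mask_png",
    "read_mask_png",
    "read_dicom_series",
]

SIDECAR_KEYS = ("venc_cms", "period_s", "pixel_spacing_mm", "n_phases")


def _affine(pixel_spacing_mm) -> np.ndarray:
    return np.diag([pixel_spacing_mm[0], pixel_spacing_mm[1], 1.0, 1.0])


def write_series(series: CinePhaseSeries, stem: str | Path) -> dict[str, Path]:
    """Write a cine series as ``<stem>_mag.nii``, ``<stem>_phase.nii`` and
    ``<stem>.json``; returns the paths written."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(series.pixel_spacing_mm)
    paths = {
        "magnitude": stem.with_name(stem.name + "_mag.nii"),
        "phase": stem.with_name(stem.name + "_phase.nii"),
        "sidecar": stem.with_suffix(".json"),
    }
    mag4 = series.magnitude[:, :, None, :].astype(np.float32)
    phs4 = series.phase[:, :, None, :].astype(np.float32)
    nib.save(nib.Nifti1Image(mag4, aff), paths["magnitude"])
    nib.save(nib.Nifti1Image(phs4, aff), paths["phase"])
    sidecar = {
        "venc_cms": series.venc_cms,
        "period_s": series.period_s,
        "pixel_spacing_mm": list(series.pixel_spacing_mm),
        "n_phases": series.n_phases,
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2))
    return paths


def read_series(
    phase_path: str | Path,
    magnitude_path: str | Path,
    sidecar_path: str | Path,
) -> CinePhaseSeries:
    """Load a cine series from the NIfTI pair plus JSON sidecar."""
    sidecar = json.loads(Path(sidecar_path).read_text())
    missing = [k for k in SIDECAR_KEYS if k not in sidecar]
    if missing:
        raise ValueError(f"sidecar missing required keys: {missing}")
    phase = np.asanyarray(nib.load(phase_path).dataobj, dtype=float)
    mag = np.asanyarray(nib.load(magnitude_path).dataobj, dtype=float)
    if phase.ndim == 4:
        phase = phase[:, :, 0, :]
    if mag.ndim == 4:
        mag = mag[:, :, 0, :]
    # float32 storage can nudge a stored -pi marginally below -pi
    phase = np.clip(phase, -np.pi, np.nextafter(np.pi, -np.inf))
    return CinePhaseSeries(
        phase=phase,
        magnitude=mag,
        venc_cms=float(sidecar["venc_cms"]),
        pixel_spacing_mm=tuple(sidecar["pixel_spacing_mm"]),
        period_s=float(sidecar["period_s"]),
    )


def write_truth(truth: PhantomTruth, path: str | Path) -> Path:
    """Serialize analytic phantom truth to JSON (mask as nested 0/1 lists)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "flow_curve_true_ul_s": truth.flow_curve_true.tolist(),
        "sv_true_ul": truth.sv_true_ul,
        "net_volume_true_ul": truth.net_volume_true_ul,
        "lumen_mask_true": truth.lumen_mask_true.astype(int).tolist(),
        "peak_velocity_cms": truth.peak_velocity_cms,
        "meta": truth.meta,
    }
    path.write_text(json.dumps(payload))
    return path


def read_truth(path: str | Path) -> PhantomTruth:
    d = json.loads(Path(path).read_text())
    return PhantomTruth(
        flow_curve_true=np.asarray(d["flow_curve_true_ul_s"]),
        sv_true_ul=d["sv_true_ul"],
        net_volume_true_ul=d["net_volume_true_ul"],
        lumen_mask_true=np.asarray(d["lumen_mask_true"], dtype=bool),
        peak_velocity_cms=d.get("peak_velocity_cms", 0.0),
        meta=d.get("meta", {}),
    )


def write_mask_png(roi: ROIMask, path: str | Path) -> Path:
    """Write an ROI as 0/255 grayscale PNG with a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray((roi.mask.astype(np.uint8)) * 255, mode="L").save(path)
    meta = {"site": roi.site, "pixel_area_mm2": roi.pixel_area_mm2}
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path


def read_mask_png(path: str | Path) -> ROIMask:
    path = Path(path)
    mask = np.asarray(Image.open(path).convert("L")) > 127
    meta = json.loads(path.with_suffix(".json").read_text())
    return ROIMask(mask=mask, site=meta["site"], pixel_area_mm2=meta["pixel_area_mm2"])


# DICOM tags searched, in order, for the velocity-encoding limit (cm/s).
# Vendor conventions vary; this import is best-effort and the sidecar/NIfTI
# path is the reference route.
_VENC_TAG_CANDIDATES = (
    (0x0019, 0x10CC),  # Siemens: venc (private)
    (0x2001, 0x101A),  # Philips: PC velocity (private, may be multi-valued)
)


def read_dicom_series(directory: str | Path, venc_cms: float | None = None) -> CinePhaseSeries:
    """Best-effort import of a directory of per-frame phase DICOM files.

    Frames are sorted by trigger time (falling back to instance number);
    pixel data are rescaled via RescaleSlope/Intercept and mapped linearly to
    radians assuming the full stored range spans ``[-pi, pi)``. Pixel spacing
    comes from the standard tag; venc is taken from ``venc_cms`` if given,
    else searched in known vendor-specific tags. The cardiac period is taken
    from NominalInterval (ms) when present, else 1 s.
    """
    import pydicom

    files = sorted(Path(directory).glob("*.dcm"))
    if len(files) < 8:
        raise ValueError("need at least 8 DICOM frames")
    datasets = [pydicom.dcmread(str(f)) for f in files]

    def sort_key(ds):
        tt = getattr(ds, "TriggerTime", None)
        return (float(tt) if tt is not None else 0.0, int(getattr(ds, "InstanceNumber", 0)))

    datasets.sort(key=sort_key)
    frames = []
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        frames.append(arr * slope + intercept)
    stack = np.stack(frames, axis=-1)
    if np.min(stack) >= 0:
        # unsigned storage: map [0, 2^bits) linearly onto [-pi, pi)
        bits = int(getattr(datasets[0], "BitsStored", 12))
        stack = (stack / 2.0**bits) * 2.0 * np.pi - np.pi
    phase = np.clip(stack, -np.pi, np.nextafter(np.pi, -np.inf))

    spacing = getattr(datasets[0], "PixelSpacing", [1.0, 1.0])
    if venc_cms is None:
        for tag in _VENC_TAG_CANDIDATES:
            if tag in datasets[0]:
                try:
                    venc_cms = float(np.ravel(datasets[0][tag].value)[0])
                    break
                except (TypeError, ValueError):
                    continue
    if venc_cms is None:
        raise ValueError("venc not found in DICOM tags; pass venc_cms explicitly")
    interval_ms = getattr(datasets[0], "NominalInterval", None)
    period_s = float(interval_ms) / 1000.0 if interval_ms else 1.0
    return CinePhaseSeries(
        phase=phase,
        magnitude=np.ones_like(phase),
        venc_cms=float(venc_cms),
        pixel_spacing_mm=(float(spacing[0]), float(spacing[1])),
        period_s=period_s,
    )
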