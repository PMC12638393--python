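# Methods

`csfpulse` re-implements, as a tested pipeline, the preoperative
phase-contrast-MRI (PC-MRI) analysis of cerebrospinal-fluid (CSF) dynamics
used to study prognosis after posterior fossa decompression in Chiari
malformation type 1: per-site CSF stroke-volume quantification from cine
phase images, the accompanying morphometric indices, and the two-group
prognostic comparison between patients with and without postoperative
headache relief. Because no patient data are deposited, a phantom simulator
and a cohort generator provide analytically known ground truth for every
stage.

## Signal model and processing chain

A cine PC-MRI acquisition of one imaging plane stores, at each of
`n_phases = 32` uniformly spaced cardiac phases, a magnitude image and a
phase image wrapped to `[-π, π)`. The velocity-encoding parameter `venc`
maps phase to through-plane velocity, `v = venc·φ/π` (cm/s); protocol
values are 10 cm/s at the aqueduct of Sylvius and 5 cm/s in the other
planes (prepontine cistern, foramen magnum, cerebellar tonsils/neuraxis,
C2–C3 subarachnoid space). Velocities beyond venc alias: the stored phase
wraps and the apparent velocity jumps by `2·venc`.

The quantification chain is:

1. **Calibration** `v = venc·φ/π` per voxel and frame.
2. **Temporal unaliasing** (optional, on by default): per-voxel 1-D phase
   unwrapping along the cardiac dimension (period `2·venc`), then the
   `±2·venc` branch with the smallest absolute temporal mean is kept —
   oscillatory CSF flow is near zero-mean, which identifies the physical
   branch. Idempotent; a no-op when no frame-to-frame jump exceeds venc.
3. **ROI segmentation**: the peak-to-peak velocity amplitude map over the
   cycle (`pulsatility map`) is thresholded at a fraction
   `threshold_frac = 0.2` of the seed voxel's amplitude, and the 4-connected
   component containing the user seed is the ROI. 4-connectivity prevents
   diagonal leakage through thin septa between CSF spaces. One parameter,
   reproducible; the published workflow only states "semi-automatic"
   segmentation, so this concretization is a design choice of this package.
4. **Background offset correction** (optional, on by default): subtracts
   the median velocity over a static-tissue mask — a single scalar per
   series by default, modelling a constant eddy-current offset without
   removing pulsatility; a per-frame mode exists. The auto static mask is
   the complement of the one-voxel-dilated ROI. The pulsatility map is
   invariant to a constant offset, so performing segmentation before offset
   correction does not change the result. If the ROI fills the grid (no
   static tissue left, e.g. pure noise input) the correction is skipped and
   flagged.
5. **Flow curve** `q(k) = Σ_{x∈ROI} v(x,k)·A_pix` (cm/s·mm² ×10 → µL/s),
   resampled by periodic linear interpolation to 32 phases when needed.
6. **Stroke volume**: the curve is integrated over one period by the
   trapezoidal rule after inserting linearly interpolated zero crossings
   (a plain trapezoid on 32 samples systematically clips the directional
   volumes near sign changes). With forward/backward displaced volumes
   `V⁺ = ∫max(q,0)dt` and `V⁻ = ∫max(−q,0)dt`:
   `SV = (V⁺+V⁻)/2` (µL per cardiac cycle) and `net = V⁺−V⁻`.

**SV convention.** The source workflow only says the flow curve "is
integrated"; `SV = (V⁺+V⁻)/2`, the mean of the two directional displaced
volumes, is the common convention for oscillatory CSF flow and is symmetric
in flow direction. It is isolated in one function so an alternative (e.g.
maximum excursion of the cumulative displaced volume) can be swapped.
Consequence, stated rather than hidden: purely unidirectional flow yields
`SV = total displaced volume / 2`.

## Phantom simulator

The phantom emulates pulsatile laminar flow through a small lumen in static
tissue: circle or annulus cross-section; plug or parabolic (Poiseuille-type)
profile normalized so the area-weighted lumen mean equals the waveform value
(circle: `2·v̄·(1−r²/R²)`; annulus: `1.5·v̄·(1−ρ²)` in the normalized gap
coordinate); mean-lumen velocity a finite sine series
`v̄(t) = Σ A_j sin(2π h_j t/T + φ_j)`. The stored phase is
`π·v/venc + offset + noise`, wrapped exactly as a scanner would store it,
with i.i.d. Gaussian phase noise (identical in lumen and tissue — no coil
physics) and an optional constant background offset. Voxel membership is by
voxel center. Analytic truth accompanies every series: `Q(t) = A_lumen·v̄(t)`
and the stroke volume by ≥4096-sample quadrature of the closed-form curve.

Defaults are chosen to mimic the studied acquisition: 32 cardiac phases,
venc 10 cm/s (aqueduct plane), period 1 s, lumen radius 1.5 mm (aqueduct
calibre), 0.3 mm in-plane spacing (typical interpolated PC-MRI resolution),
1 cm/s mean-velocity amplitude giving the closed-form
`SV = πR²·v·T/π ≈ 22.5 µL`. Not modelled: Womersley profiles, k-space
simulation, gating jitter, through-plane angulation; the waveform is sampled
exactly at 32 uniform phases (no gating-interpolation error).

**Known bias of the segmented chain.** Thresholding a parabolic profile at
`f = 0.2` of the centerline amplitude excludes the slow outer ring and loses
exactly `f² = 4%` of the flow; partial-volume recovery is deliberately out
of scope. End-to-end recovery on a noise-free Poiseuille phantom is
therefore ≈ −4–5% once rasterization has converged (the chain checks use
0.1 mm grids for this reason); at the realistic 0.3 mm default spacing the
same check reads ≈ −6%, and plug-profile phantoms recover within ~2% at any
spacing. Mild phase noise (SD 0.05 rad) partially refills the excluded ring
and the mean absolute error drops to ~1–3% across seeds. The Dice overlap
between segmented and true lumen stays above 0.9 in those conditions. With
zero flow and noise only, a spurious ROI grown from the noisiest voxel
yields SV below ~5 µL at noise SD 0.05 rad and venc 10 cm/s (the documented
noise floor for those settings).

## Cohort generator

Per-patient stroke volumes are drawn per site and outcome group from normal
distributions truncated at 0 µL (SVs are nonnegative and the reference SDs
are comparable to the means). The default parameters are the pilot cohort's
published group summaries (n = 12 relieved vs 29 not relieved), e.g.
aqueduct 65 ± 45 vs 32 ± 24 µL/CC and C2–C3 485 ± 163 vs 613 ± 166 µL/CC.
Truncation shifts the realized means upward (≈ +6.8 µL for the 65 ± 45
group, ≈ +4.3 µL for 32 ± 24); `truncated_moments` returns the analytic
truncated mean/SD, and parameter-recovery checks are made against those,
since at n = 600/group the truncation bias exceeds 3 standard errors of the
mean for the aqueduct rows. Morphometrics (Evans index ~N(0.28, 0.03),
narrowest aqueduct area ~N(4.0, 1.5) mm²) are drawn identically in both
groups, emulating their observed non-discrimination; outcome columns are
synthesized consistently with the group label (relieved ⇔ VAS drop > 2 with
quality-of-life improvement) and CCOS totals land in the 13–16 "improved"
band for ~93% of the cohort. Generation is fully determined by the seed.

What passing tests on these cohorts do **not** show: real SV distributions
need not be truncated-normal, sites are drawn independently here whereas
real per-patient SVs are correlated along the craniospinal axis, and no
measurement error links the imaging chain to the cohort tables.

## Statistics

* **Relief**: VAS reduction strictly greater than 2 points **and**
  quality-of-life improvement. **CCOS improvement**: total score 13–16.
  Rates are reported to one decimal (38/41 → 92.7%).
* **Normality**: one-sample Kolmogorov–Smirnov distance against a normal
  with the sample's own mean/SD (plug-in). Classic KS p-values are
  conservative under plug-in estimation (the Lilliefors correction is not
  applied); this mirrors common clinical practice and is stated in the API
  docs.
* **t-tests**: implemented from the closed-form statistics in both the
  Welch (unequal-variance, Welch–Satterthwaite df) and pooled-variance
  (classic Student) forms, from raw samples or published summary
  statistics. On the reference aqueduct row (12: 65±45 vs 29: 32±24) Welch
  gives t ≈ 2.40, df ≈ 13.7, p ≈ 0.031 — matching the published starred
  0.03 — while the pooled form gives p ≈ 0.004; on the C2–C3 row Welch
  gives p ≈ 0.034 (also printed 0.03). The published analysis is labelled
  "Student's t-test", but only the Welch form reproduces the printed
  p-values, so **Welch is the default** and each result records the variant
  used.
* **Mann–Whitney U**: exact two-sided p by enumeration of the U null
  distribution (Gaussian-binomial generating-function counts) when
  `n1+n2 ≤ 12` with no ties; otherwise the normal approximation with tie
  correction and 0.5 continuity correction. Verified against exhaustive
  permutation for every no-tie arrangement with `n1+n2 ≤ 10`.
* **Per-variable routing** (`compare_cohort`): stroke-volume sites use the
  t-test when both groups pass KS normality at α = 0.05, else Mann–Whitney;
  Evans index and aqueduct area always use Mann–Whitney. Significance at
  p ≤ 0.05; no multiple-testing correction by default (matching the
  reference analysis), with an optional Holm adjustment for methodological
  comparison. Under a normal null at n = 12 vs 29 the pipeline's type-I
  error is ≈ 0.05 (measured over 2000 simulations).
* **Dichotomization**: the four observed exclusivity cutoffs (aqueduct SV
  > 100 µL/CC relieved-only, < 18 not-relieved-only; C2–C3 < 300
  relieved-only, > 800 not-relieved-only) are checked per table and
  reported with per-group counts; exclusivity is vacuously true when no
  patient crosses a cutoff.

## Numerical choices and edge cases

* Coordinates are (row, col), 0-based, voxel centers at integer positions;
  polygon ROIs use the even-odd rule on voxel centers and reject
  zero-area polygons.
* The zero-crossing-subdivided trapezoid agrees with 10⁶-sample quadrature
  within 0.5% for fundamental-dominated waveforms of up to three harmonics
  (the physiological class for CSF flow curves); the bound degrades when
  higher harmonics rival the fundamental.
* Unaliasing branch ties (constant series at exactly ±venc) resolve toward
  the zero-offset branch via round-half-to-even; degenerate t-tests (both
  SDs zero, equal means) return t = 0, p = 1.
* `narrowest_slice` ties resolve to the smallest slice index. Evans index
  requires width < diameter.
* Site keys: `aqu, ppc, fm, nevrax, c2c3`, with `tonsils` accepted as an
  alias of `nevrax` (both names occur in the literature for the same
  level).
* Problem sizes used by the shipped checks: phantoms up to 48×48×32 voxels,
  2000-replicate null simulations at n = 12 vs 29, 600-patient-per-group
  recovery cohorts — sizes at which every Monte-Carlo bound above is stable
  across seeds.

## Limitations

Arterial/venous hemodynamics, surgical variables, spatial (2-D) phase
unwrapping, Maxwell-term/gradient-nonlinearity corrections, atlas-based or
3-D segmentation, and predictive modelling of relief (ROC, classifiers) are
all out of scope. The DICOM importer is best-effort (vendor venc tags vary)
and the NIfTI + JSON sidecar route is the reference input path.
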